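"""Synthetic subject cohorts with controllable group effects.

Emulates a two-group study (healthy controls vs progressive-MS
patients) at the default sizes n = 24 HC / 42 PMS.  Each network metric
is drawn from the linear, homoscedastic model the downstream ANCOVA
assumes:

``metric = baseline + shift*sd*group + lambda*sd*z_density
           + beta_age*(age - mean age) + beta_sex*sex + noise``

where ``z_density`` is the subject's standardized density value
(including its own group shift), so ``lambda`` routes a *density-
mediated* group effect through the density metric while ``shift``
injects a *direct* effect.  Covariates: age (years), sex (F/M),
T2 lesion volume (mL, near zero in HC), sensory-motor grey-matter
fraction.  Clinical outcome scores are linear in chosen metrics plus
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import InsufficientSampleError, ParameterError

__all__ = ["MetricEffect", "OutcomeSpec", "EffectSpec", "simulate_cohort",
           "default_effect_spec"]


@dataclass(frozen=True)
class MetricEffect:
    """Generative parameters of one network metric.

    ``group_shift_sd`` is the PMS-minus-HC mean difference in SD units
    (negative = lower in patients); ``density_loading`` couples the
    metric to the standardized density value (mediation path).
    """

    baseline: float
    sd: float
    group_shift_sd: float = 0.0
    beta_age: float = 0.0
    beta_sex: float = 0.0
    density_loading: float = 0.0


@dataclass(frozen=True)
class OutcomeSpec:
    """Clinical score: intercept + sum(loading * metric) + noise."""

    intercept: float
    loadings: dict = field(default_factory=dict)  # metric -> coefficient
    noise_sd: float = 1.0


@dataclass(frozen=True)
class EffectSpec:
    """Full cohort-generating specification."""

    metrics: dict = field(default_factory=dict)    # name -> MetricEffect
    outcomes: dict = field(default_factory=dict)   # name -> OutcomeSpec
    age_mean: float = 54.0
    age_sd: float = 10.0
    prob_male: float = 0.45
    t2lv_hc: tuple[float, float] = (0.4, 0.2)      # mean, sd (mL), clipped >= 0
    t2lv_pms_log: tuple[float, float] = (2.2, 0.6)  # lognormal params (mL)
    gmf_mean: float = 0.055
    gmf_group_delta: float = -0.004
    gmf_sd: float = 0.003


def default_effect_spec(density_shift: float = -1.0,
                        direct_shift: float = -1.0,
                        mediation: float = 0.0) -> EffectSpec:
    """A study-like spec: all six global metrics, lower in patients.

    ``density_shift`` moves density; ``direct_shift`` moves the other
    metrics directly; ``mediation`` routes their group difference through
    density instead.
    """
    metrics = {
        "density": MetricEffect(0.70, 0.08, group_shift_sd=density_shift,
                                beta_age=-0.002),
        "modularity": MetricEffect(0.35, 0.05, group_shift_sd=-direct_shift,
                                   density_loading=-mediation),
        "global_efficiency": MetricEffect(2000.0, 250.0,
                                          group_shift_sd=direct_shift,
                                          beta_age=-3.0,
                                          density_loading=mediation),
        "clustering_coefficient": MetricEffect(0.45, 0.06,
                                               group_shift_sd=direct_shift,
                                               density_loading=mediation),
        "mean_strength": MetricEffect(3000.0, 450.0,
                                      group_shift_sd=direct_shift,
                                      beta_age=-5.0,
                                      density_loading=mediation),
        "assortativity": MetricEffect(-0.10, 0.10, group_shift_sd=direct_shift,
                                      density_loading=mediation),
    }
    outcomes = {
        "edss": OutcomeSpec(6.0, {"global_efficiency": -0.004}, noise_sd=0.8),
        "nhpt": OutcomeSpec(35.0, {"mean_strength": -0.004}, noise_sd=4.0),
        "t25fw": OutcomeSpec(12.0, {"density": -6.0}, noise_sd=2.5),
    }
    return EffectSpec(metrics=metrics, outcomes=outcomes)


def simulate_cohort(n_hc: int = 24, n_pms: int = 42,
                    effect_spec: EffectSpec | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Draw one cohort table; deterministic given the seed.

    Columns: subject_id, group (HC/PMS), age, sex (F/M),
    t2_lesion_volume, smn_gmf, the outcome scores, and one column per
    metric in the spec.
    """
    if n_hc < 3 or n_pms < 3:
        raise InsufficientSampleError("need at least 3 subjects per group")
    if effect_spec is None:
        effect_spec = default_effect_spec()
    if "density" not in effect_spec.metrics and any(
            m.density_loading != 0 for m in effect_spec.metrics.values()):
        raise ParameterError("density_loading requires a density metric")
    rng = substream(seed, "cohort")
    n = n_hc + n_pms
    group = np.concatenate([np.zeros(n_hc), np.ones(n_pms)])
    age = np.clip(rng.normal(effect_spec.age_mean, effect_spec.age_sd, n),
                  20.0, 80.0)
    sex = (rng.random(n) < effect_spec.prob_male).astype(float)
    t2 = np.where(
        group == 0,
        np.clip(rng.normal(*effect_spec.t2lv_hc, n), 0.0, None),
        rng.lognormal(*effect_spec.t2lv_pms_log, n))
    gmf = np.clip(rng.normal(effect_spec.gmf_mean
                             + effect_spec.gmf_group_delta * group,
                             effect_spec.gmf_sd), 1e-3, 0.999)

    age_c = age - effect_spec.age_mean
    values: dict[str, np.ndarray] = {}

    def draw(name: str, eff: MetricEffect, z_density: np.ndarray | None):
        lam = eff.density_loading
        resid_scale = float(np.sqrt(max(0.0, 1.0 - lam**2)))
        v = (eff.baseline + eff.group_shift_sd * eff.sd * group
             + eff.beta_age * age_c + eff.beta_sex * sex
             + (lam * eff.sd * z_density if z_density is not None and lam else 0.0)
             + resid_scale * eff.sd * rng.standard_normal(n))
        values[name] = v

    # density first so other metrics can load on it
    if "density" in effect_spec.metrics:
        draw("density", effect_spec.metrics["density"], None)
        d = effect_spec.metrics["density"]
        z_density = (values["density"] - d.baseline) / d.sd
    else:
        z_density = None
    for name, eff in effect_spec.metrics.items():
        if name == "density":
            continue
        draw(name, eff, z_density)

    out = {
        "subject_id": [f"sub-{i+1:03d}" for i in range(n)],
        "group": np.where(group == 0, "HC", "PMS"),
        "age": age,
        "sex": np.where(sex == 0, "F", "M"),
        "t2_lesion_volume": t2,
        "smn_gmf": gmf,
    }
    for name, spec in effect_spec.outcomes.items():
        score = spec.intercept + spec.noise_sd * rng.standard_normal(n)
        for metric, loading in spec.loadings.items():
            score = score + loading * values[metric]
        out[name] = score
    out.update(values)
    return pd.DataFrame(out)
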
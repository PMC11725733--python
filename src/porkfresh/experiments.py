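"""Study-level simulation experiments.

Two repeated-seed experiments probe the pipeline's scientific claims:

* ``stepwise_recovery_experiment`` — can stepwise selection with the
  collinearity gate re-discover the generating freshness equations from
  n = 25 chemistry rows among distractor metabolites?
* ``combination_experiment`` — does the stacked combination model beat
  the spectra-only indicator model when indicators reach the spectra only
  through band-limited metabolite signatures buried under strong
  indicator-independent nuisance?  The regime mirrors the study's
  operating point: few latent variables (the reference models used 2-4)
  and heavy scatter/nuisance, with a metabolite-ablation control in which
  the stacked columns are replaced by matched-variance noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cascade import (
    CascadeConfig,
    build_state,
    combination_model,
    run_model2,
    run_model3,
)
from .design import GeneratorConfig, Signature, StudyDesign
from .equations import TBC_EQUATION, VBN_EQUATION
from .stepwise import stepwise_select
from .synthetic import gen_metabolite_profiles

__all__ = [
    "strong_nuisance_generator",
    "combination_experiment",
    "stepwise_recovery_experiment",
]

_EQUATION_TERMS = {
    "TBC": ("lysine", "malate"),
    "VBN": ("methionine", "niacinamide"),
}
_EQUATIONS = {"TBC": TBC_EQUATION, "VBN": VBN_EQUATION}


def strong_nuisance_generator(seed: int) -> GeneratorConfig:
    """Generator settings with indicator-independent spectral nuisance
    overlapping the metabolite bands, plus elevated sensor noise, so the
    spectra-to-indicator inversion is genuinely hard."""
    sigs = list(GeneratorConfig().signature_library) + [
        Signature(947.0, 30.0, "moisture", 0.06),
        Signature(1214.0, 35.0, "fat", 0.05),
        Signature(1471.0, 55.0, "moisture", 0.05),
        Signature(1310.0, 50.0, "fat", 0.04),
        Signature(560.0, 70.0, "myoglobin", 0.05),
        Signature(1500.0, 60.0, "myoglobin", 0.04),
    ]
    return GeneratorConfig(
        seed=seed,
        signature_library=tuple(sigs),
        sensor_noise_sd=0.04,
        latent_sd=1.2,
        scatter_sd=0.12,
    )


def combination_experiment(
    seeds,
    n_augment: int = 3000,
    max_lv: int = 3,
    preprocessing_grid: tuple[str, ...] = ("snv",),
    design: StudyDesign | None = None,
) -> pd.DataFrame:
    """Paired-seed comparison of Model 4 against Model 3.

    For every seed, generates data under :func:`strong_nuisance_generator`,
    runs Models 2-4 at a small latent-variable budget, and records the
    prediction-R^2 delta of the combination model and of its
    metabolite-ablation control (stacked columns replaced by
    matched-variance Gaussian noise).  One row per (seed, indicator).
    """
    design = design or StudyDesign()
    rows = []
    for seed in seeds:
        cfg = CascadeConfig(
            n_augment=n_augment,
            max_lv_spectra=max_lv,
            max_lv_metabolites=8,
            preprocessing_grid=preprocessing_grid,
        )
        state = build_state(design, strong_nuisance_generator(seed), cfg)
        mets = sorted({m for t in _EQUATION_TERMS.values() for m in t})
        m2 = run_model2(state, mets)
        m3 = run_model3(state, list(_EQUATION_TERMS))
        rng = np.random.default_rng([seed, 777])
        for ind, terms in _EQUATION_TERMS.items():
            met_pred = np.column_stack(
                [
                    m2[t]["grid"][m2[t]["best"]].pred_values
                    for t in terms
                ]
            )
            r3 = m3[ind]["grid"][m3[ind]["best"]].metrics.r2p
            real = combination_model(
                state, ind, list(terms), met_pred, model3_r2p=r3
            )
            noise = rng.normal(size=met_pred.shape) * met_pred.std(
                axis=0, ddof=1
            )
            ablated = combination_model(
                state,
                ind,
                [f"noise:{t}" for t in terms],
                noise,
                model3_r2p=r3,
            )
            rows.append(
                {
                    "seed": seed,
                    "indicator": ind,
                    "model3_r2p": r3,
                    "model4_r2p": real["grid"][real["best"]].metrics.r2p,
                    "delta": real["delta_r2p"],
                    "delta_ablated": ablated["delta_r2p"],
                }
            )
    return pd.DataFrame(rows)


def stepwise_recovery_experiment(
    seeds,
    noise_frac: float = 0.03,
    n_distractors: int = 10,
    coef_rtol: float = 0.10,
    design: StudyDesign | None = None,
) -> pd.DataFrame:
    """Support- and coefficient-recovery of the freshness equations.

    Per seed and equation: generate the n = 25 metabolite table, build the
    response from the reference equation plus Gaussian noise with sd =
    ``noise_frac`` x the signal sd, offer the two generating metabolites
    among ``n_distractors`` randomly drawn others, and run stepwise
    selection.  Success requires the exact generating support and every
    coefficient within ``coef_rtol`` of truth.
    """
    design = design or StudyDesign()
    rows = []
    for seed in seeds:
        met = gen_metabolite_profiles(design, GeneratorConfig(seed=seed))
        rng = np.random.default_rng([seed, 99])
        for ind, terms in _EQUATION_TERMS.items():
            eq = _EQUATIONS[ind]
            others = [
                c
                for c in met.columns
                if c not in ("day", "replicate") and c not in terms
            ]
            distractors = list(
                np.array(others)[
                    rng.choice(len(others), n_distractors, replace=False)
                ]
            )
            signal = eq.intercept + sum(
                coef * met[name] for name, coef in eq.coefficients.items()
            )
            y = signal + rng.normal(size=len(met)) * noise_frac * signal.std()
            res = stepwise_select(met[list(terms) + distractors], y)
            support_ok = set(res.terms) == set(terms)
            coef_ok = support_ok and all(
                abs(res.coefficients[t] - eq.coefficients[t])
                <= coef_rtol * abs(eq.coefficients[t])
                for t in terms
            )
            rows.append(
                {
                    "seed": seed,
                    "indicator": ind,
                    "support_ok": support_ok,
                    "recovered": coef_ok,
                    "terms": ",".join(res.terms),
                }
            )
    return pd.DataFrame(rows)
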
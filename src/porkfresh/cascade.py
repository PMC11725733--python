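"""The four-model freshness cascade.

Model 1 predicts each quality trait (TBC, VBN, pH, CIE L*/a*/b*) from the
NMR metabolite panel by PLSR on the Monte-Carlo-augmented data; the two
best-predicted traits become the freshness indicators.  Metabolites with
VIP > 1 for an indicator feed a stepwise linear regression (with VIF/CI
collinearity gate) that yields a compact freshness equation.  Model 2
predicts each equation metabolite from the preprocessed spectra, Model 3
predicts the indicators from spectra alone, and Model 4 — the combination
model — stacks the Model-2 predicted concentrations next to the spectra of
the shared prediction set, re-splits 7:3 and reports the improvement of
its prediction R^2 over Model 3.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import GeneratorConfig, StudyDesign
from .errors import ConfigurationError, DomainError
from .pls import (
    MetricSet,
    PLSRFit,
    compute_metrics,
    fit_plsr,
    pearson_pattern,
    plsda_vip,
    predict_plsr,
    select_lvs,
    vip_scores,
)
from .preprocess import PREPROCESSING_NAMES, l2_normalize, msc, snv, trim_wavelengths
from .resample import mc_augment, split_cal_pred
from .stepwise import StepwiseResult, stepwise_select
from .synthetic import (
    QUALITY_TRAITS,
    gen_metabolite_profiles,
    gen_quality,
    gen_spectra,
)

__all__ = [
    "CascadeConfig",
    "CascadeState",
    "PrepModel",
    "CascadeReport",
    "build_state",
    "run_model1",
    "select_freshness_indicators",
    "select_metabolites_by_vip",
    "fit_equations",
    "run_model2",
    "run_model3",
    "combination_model",
    "run_model4",
    "compare_models",
    "run_all",
]


@dataclass(frozen=True)
class CascadeConfig:
    """Pipeline settings; the printed study defaults."""

    n_augment: int = 10_000
    alpha: float = 0.05
    split_ratio: float = 0.7
    cv_splits: int = 10
    max_lv_spectra: int = 20
    max_lv_metabolites: int = 10
    vip_threshold: float = 1.0
    p_enter: float = 0.05
    p_remove: float = 0.10
    vif_max: float = 10.0
    ci_max: float = 15.0
    preprocessing_grid: tuple[str, ...] = PREPROCESSING_NAMES
    trim_low_nm: float = 400.0
    trim_high_nm: float = 1600.0
    n_indicators: int = 2
    group_aware_split: bool = False
    model4_y_source: str = "measured"  # or "model3"
    model4_autoscale_metabolites: bool = False

    def __post_init__(self) -> None:
        if self.model4_y_source not in ("measured", "model3"):
            raise ConfigurationError(
                f"model4_y_source must be 'measured' or 'model3', "
                f"got {self.model4_y_source!r}"
            )
        unknown = set(self.preprocessing_grid) - set(PREPROCESSING_NAMES)
        if unknown:
            raise ConfigurationError(
                f"unknown preprocessing methods: {sorted(unknown)}"
            )


@dataclass
class PrepModel:
    """One cell of the preprocessing grid for one target."""

    target: str
    preprocessing: str
    n_lv: int
    metrics: MetricSet
    fit: PLSRFit
    pred_values: np.ndarray  # predictions on the shared prediction set


@dataclass
class CascadeState:
    """Generated data plus the shared augmentation and 7:3 split."""

    design: StudyDesign
    generator: GeneratorConfig
    config: CascadeConfig
    metabolites: pd.DataFrame        # unaugmented chemistry (n = 25)
    quality: pd.DataFrame
    spectra_meta: pd.DataFrame       # per-spectrum metadata (n = 100)
    wavelengths_nm: np.ndarray       # trimmed grid
    aug: dict[str, pd.DataFrame]     # augmented metabolite/quality/spectra
    base_idx: np.ndarray
    cal_ids: np.ndarray
    pred_ids: np.ndarray

    @property
    def metabolite_names(self) -> list[str]:
        return [
            c
            for c in self.metabolites.columns
            if c not in ("day", "replicate")
        ]

    def xy(
        self, block: str, ids: np.ndarray, columns=None
    ) -> np.ndarray:
        df = self.aug[block].loc[ids]
        return (df if columns is None else df[columns]).to_numpy(float)


def _stream(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([seed, *tags])


def build_state(
    design: StudyDesign,
    generator: GeneratorConfig,
    config: CascadeConfig,
) -> CascadeState:
    """Generate the paired tables, trim the spectral range, replicate
    chemistry across the spectral observations, augment, and split."""
    metabolites = gen_metabolite_profiles(design, generator)
    quality = gen_quality(metabolites, generator)
    spectra, _scans = gen_spectra(metabolites, quality, design, generator)
    spectra = trim_wavelengths(spectra, config.trim_low_nm, config.trim_high_nm)

    chem_ids = spectra.meta["chem_id"].to_numpy()
    met_cols = [
        c for c in metabolites.columns if c not in ("day", "replicate")
    ]
    met_block = metabolites.loc[chem_ids, met_cols].set_axis(
        spectra.meta.index
    )
    qual_block = quality.loc[chem_ids, list(QUALITY_TRAITS)].set_axis(
        spectra.meta.index
    )
    spec_block = pd.DataFrame(
        spectra.reflectance,
        index=spectra.meta.index,
        columns=[f"{w:.10g}" for w in spectra.wavelengths_nm],
    )
    days = spectra.meta["day"].to_numpy()

    aug, base_idx = mc_augment(
        {
            "metabolites": met_block,
            "quality": qual_block,
            "spectra": spec_block,
        },
        days,
        config.n_augment,
        config.alpha,
        _stream(generator.seed, 10),
    )

    if config.group_aware_split:
        base_cal, _base_pred = split_cal_pred(
            np.arange(len(days)),
            config.split_ratio,
            _stream(generator.seed, 11),
        )
        in_cal = np.isin(base_idx, base_cal)
        all_ids = aug["quality"].index.to_numpy()
        cal_ids, pred_ids = all_ids[in_cal], all_ids[~in_cal]
    else:
        cal_ids, pred_ids = split_cal_pred(
            aug["quality"].index,
            config.split_ratio,
            _stream(generator.seed, 11),
        )

    return CascadeState(
        design=design,
        generator=generator,
        config=config,
        metabolites=metabolites,
        quality=quality,
        spectra_meta=spectra.meta,
        wavelengths_nm=spectra.wavelengths_nm,
        aug=aug,
        base_idx=base_idx,
        cal_ids=np.asarray(cal_ids),
        pred_ids=np.asarray(pred_ids),
    )


def _cv_r2(rmsecv: float, y_cal: np.ndarray) -> float:
    var = float(np.var(y_cal))
    return float("nan") if var == 0 else 1.0 - rmsecv**2 / var


def _fit_and_score(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    X_pred: np.ndarray,
    y_pred: np.ndarray,
    max_lv: int,
    cv_splits: int,
    scaling: str,
    variable_names: Sequence[str] | None = None,
) -> tuple[PLSRFit, int, MetricSet, np.ndarray]:
    n_lv, curve = select_lvs(
        X_cal, y_cal, max_lv, n_splits=cv_splits, scaling=scaling
    )
    fit = fit_plsr(
        X_cal, y_cal, n_lv, scaling=scaling, variable_names=variable_names
    )
    pred = predict_plsr(fit, X_pred)
    metrics = compute_metrics(
        cal=(y_cal, fit.fitted_values[:, 0]), pred=(y_pred, pred)
    )
    metrics = dataclasses.replace(
        metrics,
        rmsecv=float(curve[fit.n_lv - 1]),
        r2cv=_cv_r2(float(curve[fit.n_lv - 1]), y_cal),
    )
    return fit.with_metrics(metrics), fit.n_lv, metrics, pred


def run_model1(
    state: CascadeState,
) -> dict[str, PrepModel]:
    """PLSR per quality trait on the augmented metabolite panel
    (autoscaled), with RMSECV-selected latent variables."""
    out: dict[str, PrepModel] = {}
    names = state.metabolite_names
    X_cal = state.xy("metabolites", state.cal_ids)
    X_pred = state.xy("metabolites", state.pred_ids)
    for trait in QUALITY_TRAITS:
        y_cal = state.xy("quality", state.cal_ids, [trait])[:, 0]
        y_pred = state.xy("quality", state.pred_ids, [trait])[:, 0]
        fit, n_lv, metrics, pred = _fit_and_score(
            X_cal,
            y_cal,
            X_pred,
            y_pred,
            state.config.max_lv_metabolites,
            state.config.cv_splits,
            "autoscale",
            names,
        )
        out[trait] = PrepModel(trait, "raw", n_lv, metrics, fit, pred)
    return out


def select_freshness_indicators(
    metrics: Mapping[str, MetricSet], k: int = 2
) -> list[str]:
    """Top-k traits by prediction R^2; ties broken by R^2CV, then
    alphabetically."""
    if k > len(metrics):
        raise DomainError(
            f"k={k} exceeds the {len(metrics)} traits with metrics"
        )

    def sort_key(t: str):
        m = metrics[t]
        return (-m.r2p, -m.r2cv if np.isfinite(m.r2cv) else 0.0, t)

    return sorted(metrics, key=sort_key)[:k]


def select_metabolites_by_vip(
    fit: PLSRFit, threshold: float = 1.0
) -> list[str]:
    """Metabolites with VIP strictly above ``threshold``, input order."""
    return vip_scores(fit).selected(threshold)


def fit_equations(
    state: CascadeState,
    vip_selected: Mapping[str, Sequence[str]],
) -> dict[str, StepwiseResult]:
    """Stepwise freshness equations on the unaugmented chemistry rows."""
    cfg = state.config
    out = {}
    for indicator, candidates in vip_selected.items():
        if not candidates:
            raise DomainError(
                f"no VIP-selected metabolites for {indicator!r}"
            )
        out[indicator] = stepwise_select(
            state.metabolites[list(candidates)],
            state.quality[indicator].to_numpy(float),
            p_enter=cfg.p_enter,
            p_remove=cfg.p_remove,
            vif_max=cfg.vif_max,
            ci_max=cfg.ci_max,
        )
    return out


def _prep_cal_pred(
    name: str, X_cal: np.ndarray, X_pred: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the preprocessing on the calibration block, apply to both."""
    if name == "raw":
        return X_cal, X_pred
    if name == "snv":
        return snv(X_cal), snv(X_pred)
    if name == "normalize":
        return l2_normalize(X_cal), l2_normalize(X_pred)
    if name == "msc":
        ref = X_cal.mean(axis=0)
        return msc(X_cal, ref), msc(X_pred, ref)
    raise ConfigurationError(f"unknown preprocessing {name!r}")


def _spectral_grid(
    state: CascadeState,
    target: str,
    y_block: str,
    y_column: str,
) -> dict[str, PrepModel]:
    """Fit the preprocessing grid of PLSR models for one target whose Y
    lives in ``aug[y_block][y_column]``."""
    cfg = state.config
    X_cal_raw = state.xy("spectra", state.cal_ids)
    X_pred_raw = state.xy("spectra", state.pred_ids)
    y_cal = state.xy(y_block, state.cal_ids, [y_column])[:, 0]
    y_pred = state.xy(y_block, state.pred_ids, [y_column])[:, 0]
    wl_names = list(state.aug["spectra"].columns)

    grid: dict[str, PrepModel] = {}
    for prep in cfg.preprocessing_grid:
        X_cal, X_pred = _prep_cal_pred(prep, X_cal_raw, X_pred_raw)
        fit, n_lv, metrics, pred = _fit_and_score(
            X_cal,
            y_cal,
            X_pred,
            y_pred,
            cfg.max_lv_spectra,
            cfg.cv_splits,
            "center",
            wl_names,
        )
        grid[prep] = PrepModel(target, prep, n_lv, metrics, fit, pred)
    return grid


def _best_prep(grid: Mapping[str, PrepModel]) -> str:
    """Highest prediction R^2; ties toward the grid order."""
    best, best_r2 = None, -np.inf
    for prep, rec in grid.items():
        if rec.metrics.r2p > best_r2:
            best, best_r2 = prep, rec.metrics.r2p
    return best


def run_model2(
    state: CascadeState, metabolites: Sequence[str]
) -> dict[str, dict]:
    """HSI -> metabolite concentration, per equation metabolite, across
    the preprocessing grid; winner by prediction R^2."""
    out = {}
    for met in metabolites:
        if met not in state.aug["metabolites"].columns:
            raise DomainError(f"unknown metabolite {met!r}")
        grid = _spectral_grid(state, met, "metabolites", met)
        out[met] = {"grid": grid, "best": _best_prep(grid)}
    return out


def run_model3(
    state: CascadeState, indicators: Sequence[str]
) -> dict[str, dict]:
    """HSI -> freshness indicator, across the preprocessing grid; the
    winner also carries its VIP-over-wavelength profile."""
    out = {}
    for ind in indicators:
        grid = _spectral_grid(state, ind, "quality", ind)
        best = _best_prep(grid)
        out[ind] = {
            "grid": grid,
            "best": best,
            "vip": vip_scores(grid[best].fit),
        }
    return out


def combination_model(
    state: CascadeState,
    indicator: str,
    terms: Sequence[str],
    met_pred: np.ndarray,
    model3_r2p: float = float("nan"),
    y_all: np.ndarray | None = None,
) -> dict:
    """Fit the combination model for one indicator.

    ``met_pred`` holds the Model-2 predicted concentrations of the
    indicator's equation metabolites on the shared prediction set (one
    column per term, same row order as ``state.pred_ids``).  The combined
    set is re-split 7:3 (one shared split across indicators) and the
    preprocessing grid applies to the spectral block only; the metabolite
    columns pass through unchanged.
    """
    cfg = state.config
    pred_ids = state.pred_ids
    met_pred = np.atleast_2d(np.asarray(met_pred, float))
    if met_pred.shape != (pred_ids.size, len(terms)):
        raise DomainError(
            f"met_pred shape {met_pred.shape} != "
            f"({pred_ids.size}, {len(terms)})"
        )
    cal4_ids, pred4_ids = split_cal_pred(
        pred_ids, cfg.split_ratio, _stream(state.generator.seed, 12)
    )
    pos = pd.Index(pred_ids)
    cal4_pos = pos.get_indexer(cal4_ids)
    pred4_pos = pos.get_indexer(pred4_ids)
    spec_pred = state.xy("spectra", pred_ids)

    if y_all is None:
        y_all = state.xy("quality", pred_ids, [indicator])[:, 0]
    y_cal, y_pred = y_all[cal4_pos], y_all[pred4_pos]

    grid: dict[str, PrepModel] = {}
    for prep in cfg.preprocessing_grid:
        X_cal_s, X_pred_s = _prep_cal_pred(
            prep, spec_pred[cal4_pos], spec_pred[pred4_pos]
        )
        met_cal, met_prd = met_pred[cal4_pos], met_pred[pred4_pos]
        if cfg.model4_autoscale_metabolites:
            sd = met_cal.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            met_cal, met_prd = met_cal / sd, met_prd / sd
        X_cal = np.hstack([X_cal_s, met_cal])
        X_pred = np.hstack([X_pred_s, met_prd])
        names = list(state.aug["spectra"].columns) + [
            f"pred:{t}" for t in terms
        ]
        fit, n_lv, metrics, pred = _fit_and_score(
            X_cal,
            y_cal,
            X_pred,
            y_pred,
            cfg.max_lv_spectra,
            cfg.cv_splits,
            "center",
            names,
        )
        grid[prep] = PrepModel(indicator, prep, n_lv, metrics, fit, pred)
    best = _best_prep(grid)
    return {
        "grid": grid,
        "best": best,
        "metabolite_terms": list(terms),
        "cal_ids": np.asarray(cal4_ids),
        "pred_ids": np.asarray(pred4_ids),
        "delta_r2p": grid[best].metrics.r2p - model3_r2p,
    }


def run_model4(
    state: CascadeState,
    model2: Mapping[str, dict],
    model3: Mapping[str, dict],
    equations: Mapping[str, StepwiseResult],
) -> dict[str, dict]:
    """Combination model per indicator.

    X concatenates the (re-preprocessed) spectra of the shared prediction
    set with the Model-2 winning predictions of the indicator's equation
    metabolites; Y is the measured indicator on those samples (or the
    Model-3 predictions when configured).
    """
    cfg = state.config
    out = {}
    for ind, eq in equations.items():
        terms = list(eq.terms)
        missing = [t for t in terms if t not in model2]
        if missing:
            raise DomainError(
                f"Model 2 has no model for equation metabolites {missing} "
                f"of {ind!r}; run Model 2 first"
            )
        met_pred = np.column_stack(
            [model2[t]["grid"][model2[t]["best"]].pred_values for t in terms]
        )
        y_all = (
            model3[ind]["grid"][model3[ind]["best"]].pred_values
            if cfg.model4_y_source == "model3"
            else None
        )
        out[ind] = combination_model(
            state,
            ind,
            terms,
            met_pred,
            model3_r2p=model3[ind]["grid"][model3[ind]["best"]].metrics.r2p,
            y_all=y_all,
        )
    return out


def compare_models(
    model3: Mapping[str, dict], model4: Mapping[str, dict]
) -> pd.DataFrame:
    """Per-indicator Model-4 minus Model-3 prediction R^2, from the
    stored metric sets."""
    rows = []
    for ind in model4:
        r3 = model3[ind]["grid"][model3[ind]["best"]].metrics.r2p
        r4 = model4[ind]["grid"][model4[ind]["best"]].metrics.r2p
        rows.append(
            {
                "indicator": ind,
                "model3_r2p": r3,
                "model4_r2p": r4,
                "delta_r2p": r4 - r3,
                "verdict": "improved" if r4 > r3 else (
                    "unchanged" if r4 == r3 else "regressed"
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full pipeline report


@dataclass
class CascadeReport:
    """Everything a run produces, JSON-serializable and deterministic."""

    seed: int
    config_hash: str
    bookkeeping: dict
    model1: dict
    chosen_indicators: list[str]
    pearson_top: dict
    plsda_top: dict
    vip_selected: dict
    equations: dict
    model2: dict
    model3: dict
    model4: dict
    deltas: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _metrics_row(rec: PrepModel) -> dict:
    d = {"LVs": rec.n_lv}
    d.update(rec.metrics.as_dict())
    return d


def _grid_rows(result: Mapping[str, dict]) -> dict:
    out = {}
    for target, entry in result.items():
        out[target] = {
            "best": entry["best"],
            "grid": {
                prep: _metrics_row(rec)
                for prep, rec in entry["grid"].items()
            },
        }
    return out


def config_hash(
    design: StudyDesign, generator: GeneratorConfig, config: CascadeConfig
) -> str:
    blob = yaml.safe_dump(
        {
            "design": str(design),
            "generator": str(generator),
            "cascade": str(config),
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_all(
    design: StudyDesign | None = None,
    generator: GeneratorConfig | None = None,
    config: CascadeConfig | None = None,
) -> CascadeReport:
    """Run the entire cascade end-to-end; one master seed (the
    generator's) fixes the whole report."""
    design = design or StudyDesign()
    generator = generator or GeneratorConfig()
    config = config or CascadeConfig()

    state = build_state(design, generator, config)
    m1 = run_model1(state)
    m1_metrics = {t: rec.metrics for t, rec in m1.items()}
    indicators = select_freshness_indicators(
        m1_metrics, config.n_indicators
    )
    vip_sel = {
        ind: select_metabolites_by_vip(m1[ind].fit, config.vip_threshold)
        for ind in indicators
    }
    equations = fit_equations(state, vip_sel)
    eq_mets = sorted({t for eq in equations.values() for t in eq.terms})
    if not eq_mets:
        raise DomainError("stepwise selected no metabolites; cannot stack")
    m2 = run_model2(state, eq_mets)
    m3 = run_model3(state, indicators)
    m4 = run_model4(state, m2, m3, equations)
    comparison = compare_models(m3, m4)

    pearson_top = {
        ind: pearson_pattern(
            state.metabolites, state.quality[ind]
        )
        .head(24)
        .to_dict("records")
        for ind in indicators
    }
    plsda = plsda_vip(
        state.metabolites[state.metabolite_names].to_numpy(float),
        state.metabolites["day"].tolist(),
        variable_names=state.metabolite_names,
    )
    plsda_top = (
        plsda.as_series().sort_values(ascending=False).head(10).to_dict()
    )

    report = CascadeReport(
        seed=generator.seed,
        config_hash=config_hash(design, generator, config),
        bookkeeping={
            "n_chem": int(state.design.n_chem),
            "n_spectra": int(state.design.n_spectra),
            "n_bands": int(state.wavelengths_nm.size),
            "n_augment": int(len(state.aug["quality"])),
            "n_calibration": int(state.cal_ids.size),
            "n_prediction": int(state.pred_ids.size),
            "model4_n_calibration": int(
                next(iter(m4.values()))["cal_ids"].size
            )
            if m4
            else 0,
            "model4_n_prediction": int(
                next(iter(m4.values()))["pred_ids"].size
            )
            if m4
            else 0,
            "split_mode": "group-aware"
            if config.group_aware_split
            else "row-level",
        },
        model1={t: _metrics_row(rec) for t, rec in m1.items()},
        chosen_indicators=list(indicators),
        pearson_top=pearson_top,
        plsda_top=plsda_top,
        vip_selected=vip_sel,
        equations={
            ind: {
                "terms": list(eq.terms),
                "intercept": eq.intercept,
                "coefficients": eq.coefficients,
                "r2": eq.r2,
                "vif": eq.vif,
                "condition_indices": [float(c) for c in eq.condition_indices],
                "accepted": eq.accepted,
                "text": eq.equation(ind).to_text(),
            }
            for ind, eq in equations.items()
        },
        model2=_grid_rows(m2),
        model3={
            ind: {
                **_grid_rows({ind: entry})[ind],
                "vip_above_1_nm": [
                    float(w)
                    for w, s in zip(
                        state.wavelengths_nm, entry["vip"].scores
                    )
                    if s > 1.0
                ],
            }
            for ind, entry in m3.items()
        },
        model4={
            ind: {
                **_grid_rows({ind: entry})[ind],
                "metabolite_terms": entry["metabolite_terms"],
                "delta_r2p": float(entry["delta_r2p"]),
            }
            for ind, entry in m4.items()
        },
        deltas={
            row["indicator"]: float(row["delta_r2p"])
            for row in comparison.to_dict("records")
        },
    )
    return report
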
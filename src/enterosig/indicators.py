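"""Indicator-taxa effect-pattern analysis.

A taxon is an *indicator* of the intervention when (a) its relative
abundance differs among the study groups by a Kruskal-Wallis test after
Benjamini-Hochberg correction across taxa, and (b) at least one of a bank of
coded linear models is significant.  Each model assigns an arbitrary unit to
every group encoding one hypothesized effect shape of the treatment relative
to the disease and control conditions; the taxon's abundance is regressed on
those units, and among significant models the one with the highest effect
size (R^2 of the simple regression) gives the taxon its pattern label.
Indicator taxa are then correlated (Pearson, BH-corrected across the
indicator set) with a per-animal phenotype such as total cholesterol.

The default bank encodes six treatment-response shapes for a
(control, disease, treated) design, with units
(25, 75, 10), (25, 75, 25), (25, 75, 50), (25, 75, 75), (25, 75, 100) and
(100, 100, 10): overshooting rescue, full rescue, partial rescue, no rescue,
aggravation, and a treatment-only change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable


@dataclass(frozen=True)
class PatternModel:
    model_id: int
    label: str
    units: tuple[float, ...]  # one coded unit per group, in declared group order


@dataclass
class PatternBank:
    """Ordered bank of coded linear models, one unit per group each."""

    groups: tuple[str, ...]
    models: tuple[PatternModel, ...]

    def __post_init__(self) -> None:
        for m in self.models:
            if len(m.units) != len(self.groups):
                raise ValueError(
                    f"model {m.model_id} has {len(m.units)} units for "
                    f"{len(self.groups)} groups"
                )
            if len(set(m.units)) == 1:
                raise ValueError(f"model {m.model_id} units are all equal")

    def unit_map(self, model: PatternModel) -> dict[str, float]:
        return dict(zip(self.groups, model.units))

    def by_id(self, model_id: int) -> PatternModel:
        for m in self.models:
            if m.model_id == model_id:
                return m
        raise KeyError(f"no model with id {model_id}")


DEFAULT_MODELS = (
    PatternModel(1, "return beyond normal", (25, 75, 10)),
    PatternModel(2, "return to normal", (25, 75, 25)),
    PatternModel(3, "partial return", (25, 75, 50)),
    PatternModel(4, "no rescue", (25, 75, 75)),
    PatternModel(5, "accentuates disease effect", (25, 75, 100)),
    PatternModel(6, "treatment-only change", (100, 100, 10)),
)


def default_bank(groups: tuple[str, ...] = ("ND", "HFD", "HFD-T070")) -> PatternBank:
    """The six-model bank for a (control, disease, treated) group order."""
    if len(groups) != 3:
        raise ValueError("the default bank codes exactly three groups")
    return PatternBank(groups=tuple(groups), models=DEFAULT_MODELS)


def read_bank_tsv(path, groups: tuple[str, ...]) -> PatternBank:
    """Load a bank from a 3-column TSV: model id, label, comma-joined units."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["model_id", "label", "units"])
    models = tuple(
        PatternModel(int(r.model_id), str(r.label),
                     tuple(float(u) for u in str(r.units).split(",")))
        for r in df.itertuples()
    )
    return PatternBank(groups=tuple(groups), models=models)


# ---------------------------------------------------------------------------
# Elementary tests


def kw_test(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    if any(s.size == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    if values.size < 3:
        raise ValueError("need at least three observations in total")
    if np.ptp(values) == 0:
        return 0.0, 1.0  # scipy raises on all-identical input
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r and its two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Pattern-model fitting and indicator selection


def fit_pattern_models(values, groups, bank: PatternBank) -> pd.DataFrame:
    """OLS of abundance on each model's coded units.

    Returns one row per model with ``slope``, ``r_squared`` (the effect size
    used for model selection) and the two-sided ``p_value`` of the slope.
    Models whose coded units are constant over the observed samples are
    skipped with a warning (degenerate design).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    unknown = set(groups) - set(bank.groups)
    if unknown:
        raise ValueError(f"groups without coded units: {sorted(unknown)}")
    rows = []
    for m in bank.models:
        units = np.array([bank.unit_map(m)[g] for g in groups], dtype=float)
        if np.ptp(units) == 0:
            warnings.warn(
                f"model {m.model_id}: coded units constant over the observed "
                "samples; skipped",
                stacklevel=2,
            )
            continue
        if np.ptp(values) == 0:
            rows.append({"model_id": m.model_id, "label": m.label,
                         "slope": 0.0, "r_squared": 0.0, "p_value": 1.0})
            continue
        fit = stats.linregress(units, values)
        rows.append(
            {
                "model_id": m.model_id,
                "label": m.label,
                "slope": float(fit.slope),
                "r_squared": float(fit.rvalue**2),
                "p_value": float(fit.pvalue),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class IndicatorResult:
    """Full per-taxon record of the indicator-pattern analysis."""

    taxon: str
    h_kw: float
    p_kw: float
    q_kw: float
    model_fits: pd.DataFrame
    is_indicator: bool
    selected_model: int | None
    pattern_label: str | None
    group_means: dict
    pct_changes: dict
    phenotype_r: float | None = None
    phenotype_p: float | None = None
    phenotype_q: float | None = None


def select_indicators(
    table: AbundanceTable,
    groups: pd.Series,
    phenotype: pd.Series | None = None,
    bank: PatternBank | None = None,
    alpha: float = 0.05,
    adjust_model_p: bool = False,
    transform=None,
) -> list[IndicatorResult]:
    """Run the full indicator-taxa procedure on an abundance table.

    Per taxon: relative abundance -> Kruskal-Wallis across groups -> BH
    correction across taxa -> six-model fits; a taxon is an indicator iff
    its KW q-value < `alpha` and at least one model has p < `alpha`; among
    significant models the one with the highest R^2 is selected (ties to
    the lowest model id).  Pearson correlations with `phenotype` are
    computed for the indicator set and BH-corrected within that set.

    `transform` optionally maps the relative-abundance matrix before model
    fitting (e.g. ``np.log1p``); the KW gate always sees raw proportions
    (rank-based, so any monotone transform is irrelevant there).
    """
    if table.counts.shape[0] < 2:
        raise ValueError("need at least two taxa")
    groups = pd.Series(groups).reindex(table.samples)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    if bank is None:
        bank = default_bank(tuple(pd.unique(groups)))

    rel = table.relative_abundance()
    fit_matrix = transform(rel) if transform is not None else rel
    garr = groups.to_numpy()

    kw_rows = [kw_test(rel.loc[t].to_numpy(), garr) for t in rel.index]
    h_vals = np.array([r[0] for r in kw_rows])
    p_vals = np.array([r[1] for r in kw_rows])
    q_vals = bh_fdr(p_vals)

    results: list[IndicatorResult] = []
    for i, taxon in enumerate(rel.index):
        fits = fit_pattern_models(fit_matrix.loc[taxon].to_numpy(), garr, bank)
        pcol = fits["p_value"].to_numpy()
        if adjust_model_p and len(pcol):
            pcol = bh_fdr(pcol)
            fits = fits.assign(p_value=pcol)
        sig = fits[fits["p_value"] < alpha]
        selected = None
        label = None
        if not sig.empty:
            best = sig.sort_values(
                ["r_squared", "model_id"], ascending=[False, True]
            ).iloc[0]
            selected = int(best["model_id"])
            label = str(best["label"])
        is_ind = bool(q_vals[i] < alpha and selected is not None)
        means = rel.loc[taxon].groupby(garr).mean()
        means = means.reindex(list(bank.groups))
        pct = {}
        glist = list(bank.groups)
        for a, b in [(glist[1], glist[0]), (glist[2], glist[1]), (glist[2], glist[0])]:
            if means[b] != 0:
                pct[f"{a}_vs_{b}"] = float(100.0 * (means[a] - means[b]) / means[b])
        results.append(
            IndicatorResult(
                taxon=str(taxon),
                h_kw=float(h_vals[i]),
                p_kw=float(p_vals[i]),
                q_kw=float(q_vals[i]),
                model_fits=fits,
                is_indicator=is_ind,
                selected_model=selected if is_ind else None,
                pattern_label=label if is_ind else None,
                group_means=means.to_dict(),
                pct_changes=pct,
            )
        )

    if phenotype is not None:
        phenotype = pd.Series(phenotype).reindex(table.samples)
        indicators = [r for r in results if r.is_indicator]
        pr = []
        for r in indicators:
            x = rel.loc[r.taxon]
            mask = phenotype.notna()
            n_drop = int((~mask).sum())
            if n_drop:
                warnings.warn(
                    f"{n_drop} samples without phenotype dropped pairwise",
                    stacklevel=2,
                )
            rr, pp = pearson_correlation(x[mask].to_numpy(), phenotype[mask].to_numpy())
            r.phenotype_r, r.phenotype_p = rr, pp
            pr.append(pp)
        if pr:
            qq = bh_fdr(np.array(pr))
            for r, q in zip(indicators, qq):
                r.phenotype_q = float(q)
    return results


def indicator_table(results: list[IndicatorResult]) -> pd.DataFrame:
    """Flatten IndicatorResult records into one row per taxon."""
    rows = []
    for r in results:
        row = {
            "taxon": r.taxon,
            "h_kw": r.h_kw,
            "p_kw": r.p_kw,
            "q_kw": r.q_kw,
            "is_indicator": r.is_indicator,
            "selected_model": r.selected_model,
            "pattern_label": r.pattern_label,
            "phenotype_r": r.phenotype_r,
            "phenotype_p": r.phenotype_p,
            "phenotype_q": r.phenotype_q,
        }
        for g, m in r.group_means.items():
            row[f"mean_{g}"] = m
        for k, v in r.pct_changes.items():
            row[f"pct_{k}"] = v
        for f in r.model_fits.itertuples():
            row[f"m{f.model_id}_r2"] = f.r_squared
            row[f"m{f.model_id}_p"] = f.p_value
        rows.append(row)
    return pd.DataFrame(rows)
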
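"""Reference-database statistics over a cohort of per-eye retinal volumes.

Covers the analyses of a normative volumetry database: grouped summary
statistics (count / mean / std / min / median / max / CV) by eye side, sex
and origin; pairwise Pearson correlation summaries within and between the
zone, quadrant and slice variable families; principal component analysis of
the nine slice volumes on the covariance matrix (all variables share mm³);
two-factor MANOVA (Wilks' lambda with Rao's F approximation, via
statsmodels) and per-slice two-factor ANOVA with Type II sums of squares and
Bonferroni-corrected significance stars (thresholds divided by the nine
slice tests).

Eyes of unknown origin are excluded before any sex/origin model is fitted,
and eyes are treated as independent observations throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.multivariate.manova import MANOVA

from .oct_io import CohortTable
from .volumetry import QUADRANT_NAMES, REGION_NAMES, SLICE_NAMES, ZONE_NAMES

__all__ = [
    "SummaryStats",
    "CorrelationBlockSummary",
    "PcaResult",
    "FactorTest",
    "ManovaResult",
    "AnovaTable",
    "ReportBundle",
    "summarize",
    "correlation_block_summary",
    "pca_slices",
    "manova_slices",
    "anova_per_slice",
    "bonferroni_stars",
    "reproduce_report",
]

#: default interaction-removal significance levels: the multivariate model
#: drops the sex×origin term at 0.01; the per-slice univariate models use
#: the Bonferroni-adjusted 0.01/9.
MANOVA_INTERACTION_DROP = 0.01
ANOVA_INTERACTION_DROP = 0.01 / 9.0


def _as_df(cohort) -> pd.DataFrame:
    if isinstance(cohort, CohortTable):
        return cohort.to_dataframe()
    return pd.DataFrame(cohort).copy()


def _eye_filter(df: pd.DataFrame, eye_side: str | None) -> pd.DataFrame:
    if eye_side is None:
        return df
    if eye_side not in ("OD", "OS"):
        raise ValueError(f"eye_side must be 'OD' or 'OS', got {eye_side!r}")
    return df[df["eye"] == eye_side]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStats:
    """Summary statistics of one region in one subgroup (volumes in mm³)."""

    count: int
    mean: float
    std: float
    min: float
    median: float
    max: float
    cv: float

    @classmethod
    def from_values(cls, values) -> "SummaryStats":
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise ValueError("cannot summarise an empty group")
        mean = float(v.mean())
        std = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return cls(
            count=int(v.size),
            mean=mean,
            std=std,
            min=float(v.min()),
            median=float(np.median(v)),
            max=float(v.max()),
            cv=std / mean if mean > 0 else float("nan"),
        )


def summarize(cohort, group_keys=(), region: str = "Z1"):
    """Summary statistics for one region, overall or per subgroup.

    ``group_keys`` is a subset of {"eye", "sex", "origin"}; with no keys a
    single :class:`SummaryStats` is returned, otherwise a dict keyed by
    group tuples. Empty groups are simply absent. The standard deviation
    uses the n−1 denominator.
    """
    df = _as_df(cohort)
    if region not in REGION_NAMES:
        raise ValueError(f"unknown region {region!r}")
    bad = set(group_keys) - {"eye", "sex", "origin"}
    if bad:
        raise ValueError(f"unsupported group keys: {sorted(bad)}")
    if not group_keys:
        return SummaryStats.from_values(df[region])
    out = {}
    for key, sub in df.groupby(list(group_keys), observed=True, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        out[key] = SummaryStats.from_values(sub[region])
    return out


# ---------------------------------------------------------------------------
# correlation blocks
# ---------------------------------------------------------------------------

_BLOCKS = {
    "among_zones": (ZONE_NAMES, ZONE_NAMES),
    "among_quadrants": (QUADRANT_NAMES, QUADRANT_NAMES),
    "among_slices": (SLICE_NAMES, SLICE_NAMES),
    "zones_and_quadrants": (ZONE_NAMES, QUADRANT_NAMES),
    "zones_and_slices": (ZONE_NAMES, SLICE_NAMES),
    "quadrants_and_slices": (QUADRANT_NAMES, SLICE_NAMES),
}


@dataclass
class CorrelationBlockSummary:
    """Five-number summaries of pairwise Pearson r, per variable-family block.

    Within-family blocks use unordered distinct pairs (3, 6 and 36 pairs for
    zones, quadrants and slices); between-family blocks use the full cross
    product (12, 27, 36). Undefined coefficients (zero-variance variables)
    are excluded and counted.
    """

    blocks: dict
    n_records: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.blocks).T


def correlation_block_summary(cohort, eye_side: str | None = None) -> CorrelationBlockSummary:
    """Pairwise Pearson correlations among and between Z, Q and S variables.

    All eyes are pooled by default (``eye_side=None``); pass "OD"/"OS" to
    restrict to one side.
    """
    df = _eye_filter(_as_df(cohort), eye_side)
    if len(df) < 3:
        raise ValueError("need at least 3 records for correlation analysis")
    X = df[list(REGION_NAMES)].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    # degenerate: no variance beyond float rounding of a constant column
    degenerate = sd <= 1e-12 * np.maximum(np.abs(X.mean(axis=0)), 1e-30)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C[degenerate, :] = np.nan
    C[:, degenerate] = np.nan
    idx = {n: i for i, n in enumerate(REGION_NAMES)}
    blocks = {}
    for name, (fam_a, fam_b) in _BLOCKS.items():
        if fam_a is fam_b:
            pairs = list(itertools.combinations(fam_a, 2))
        else:
            pairs = list(itertools.product(fam_a, fam_b))
        r = np.array([C[idx[a], idx[b]] for a, b in pairs])
        defined = r[np.isfinite(r)]
        stats = {
            k: (float(f(defined)) if defined.size else float("nan"))
            for k, f in (
                ("mean", np.mean),
                ("min", np.min),
                ("q25", lambda v: np.percentile(v, 25)),
                ("q50", lambda v: np.percentile(v, 50)),
                ("q75", lambda v: np.percentile(v, 75)),
                ("max", np.max),
            )
        }
        stats["n_pairs"] = len(pairs)
        stats["n_excluded"] = int(len(pairs) - defined.size)
        blocks[name] = stats
    return CorrelationBlockSummary(blocks=blocks, n_records=len(df))


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    """Eigendecomposition of the S1–S9 sample covariance matrix.

    ``coefficients[:, k]`` is the unit-norm eigenvector of the (k+1)-th
    principal component, signed so its largest-magnitude entry is positive.
    No standardisation is applied — the nine slices share mm³ units.
    """

    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    cumulative_fraction: np.ndarray
    coefficients: np.ndarray
    eye_side: str | None
    n_records: int

    def coefficients_table(self, n_components: int = 3) -> pd.DataFrame:
        return pd.DataFrame(
            self.coefficients[:, :n_components].T,
            index=[f"PC{i + 1}" for i in range(n_components)],
            columns=list(SLICE_NAMES),
        )


def pca_slices(cohort, eye_side: str | None = "OD") -> PcaResult:
    """PCA of the nine slice volumes for one eye side (or pooled)."""
    df = _eye_filter(_as_df(cohort), eye_side)
    n = len(df)
    if n < 10:
        raise ValueError(
            f"need at least 10 records for PCA of 9 variables, got {n}"
        )
    X = df[list(SLICE_NAMES)].to_numpy(dtype=float)
    cov = np.cov(X, rowvar=False, ddof=1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = np.clip(w[order], 0.0, None), v[:, order]
    # deterministic sign: largest-magnitude loading positive
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(9)])
    flip[flip == 0] = 1.0
    v = v * flip
    total = w.sum()
    frac = w / total if total > 0 else np.full(9, np.nan)
    return PcaResult(
        eigenvalues=w,
        explained_fraction=frac,
        cumulative_fraction=np.cumsum(frac),
        coefficients=v,
        eye_side=eye_side,
        n_records=n,
    )


# ---------------------------------------------------------------------------
# MANOVA / ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorTest:
    """Wilks' lambda test of one factor in the multivariate model."""

    wilks_lambda: float
    F: float
    df_num: float
    df_den: float
    p: float


@dataclass
class ManovaResult:
    factors: dict  # factor name -> FactorTest
    interaction_p: float
    interaction_dropped: bool
    eye_side: str | None
    n_records: int


def _known_origin(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["origin"].isin(["Mauritius", "Asia"])]


def _check_factors(df: pd.DataFrame, factors) -> None:
    for f in factors:
        levels = df[f].nunique()
        if levels < 2:
            raise ValueError(f"factor {f!r} has {levels} level(s); need at least 2")


def _wilks_row(mv_results, term: str) -> FactorTest:
    stat = mv_results.results[term]["stat"]
    row = stat.loc["Wilks' lambda"]
    return FactorTest(
        wilks_lambda=float(row["Value"]),
        F=float(row["F Value"]),
        df_num=float(row["Num DF"]),
        df_den=float(row["Den DF"]),
        p=float(row["Pr > F"]),
    )


def manova_slices(
    cohort,
    eye_side: str | None = "OD",
    factors: tuple = ("sex", "origin"),
    drop_interaction_at: float = MANOVA_INTERACTION_DROP,
) -> ManovaResult:
    """Two-factor MANOVA of S1–S9 on sex and origin.

    Unknown-origin eyes are excluded first. The model is fitted with the
    sex×origin interaction; if the interaction's Wilks p-value is at or
    above ``drop_interaction_at`` the additive model is refitted and the
    factor tests are reported from it.
    """
    df = _known_origin(_eye_filter(_as_df(cohort), eye_side))
    _check_factors(df, factors)
    endog = " + ".join(SLICE_NAMES)
    terms = [f"C({f})" for f in factors]
    full = MANOVA.from_formula(
        f"{endog} ~ {terms[0]} * {terms[1]}", data=df
    ).mv_test()
    inter = _wilks_row(full, f"{terms[0]}:{terms[1]}")
    dropped = inter.p >= drop_interaction_at
    fitted = (
        MANOVA.from_formula(f"{endog} ~ {terms[0]} + {terms[1]}", data=df).mv_test()
        if dropped
        else full
    )
    return ManovaResult(
        factors={f: _wilks_row(fitted, f"C({f})") for f in factors},
        interaction_p=inter.p,
        interaction_dropped=bool(dropped),
        eye_side=eye_side,
        n_records=len(df),
    )


def bonferroni_stars(p: float, m: int = 9) -> str:
    """Significance stars under Bonferroni division of the usual levels.

    "***" for p < 0.001/m, "**" for p < 0.01/m, "*" for p < 0.05/m, else ""
    (strict inequalities).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p!r}")
    if m < 1:
        raise ValueError("m must be >= 1")
    for level, stars in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
        if p < level / m:
            return stars
    return ""


@dataclass
class AnovaTable:
    """Per-slice two-factor ANOVA results with Bonferroni stars."""

    cells: dict  # (slice, factor) -> {"F":, "p":, "stars":}
    interaction_p: dict  # slice -> p of the sex×origin term in the full model
    eye_side: str | None
    n_records: int

    def stars_frame(self) -> pd.DataFrame:
        factors = sorted({f for (_, f) in self.cells})
        return pd.DataFrame(
            {
                s: {f: self.cells[(s, f)]["stars"] for f in factors}
                for s in SLICE_NAMES
            }
        )

    def significant_slices(self, factor: str) -> list:
        return [
            s for s in SLICE_NAMES if self.cells[(s, factor)]["stars"] != ""
        ]


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of Y (n×k) on design X (n×p), per column."""
    Q, _ = np.linalg.qr(X)
    return np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", Q.T @ Y, Q.T @ Y)


def _type2_two_factor(
    Y: np.ndarray, a: np.ndarray, b: np.ndarray, drop_interaction_at: float
):
    """Type II two-factor ANOVA for every column of Y at once.

    ``a`` and ``b`` are binary (two-level) factor indicators. Each response
    is modelled with the a×b interaction; where the interaction p-value is
    at or above ``drop_interaction_at`` the additive model's Type II tests
    are reported instead (matching the interaction-removal workflow).
    Returns per-column dicts for factor A, factor B and the interaction p.
    Numerically identical to statsmodels' ``anova_lm(..., typ=2)``.
    """
    from scipy import stats

    n = Y.shape[0]
    one = np.ones((n, 1))
    a = a.reshape(-1, 1).astype(float)
    b = b.reshape(-1, 1).astype(float)
    X_a = np.hstack([one, a])
    X_b = np.hstack([one, b])
    X_add = np.hstack([one, a, b])
    X_full = np.hstack([one, a, b, a * b])
    rss_a, rss_b = _rss(X_a, Y), _rss(X_b, Y)
    rss_add, rss_full = _rss(X_add, Y), _rss(X_full, Y)

    df_full = n - X_full.shape[1]
    df_add = n - X_add.shape[1]
    mse_full = rss_full / df_full
    mse_add = rss_add / df_add
    with np.errstate(invalid="ignore", divide="ignore"):
        F_int = (rss_add - rss_full) / mse_full
        p_int = stats.f.sf(F_int, 1, df_full)
        # Type II numerators: each factor against the model of the other
        F_a_full = (rss_b - rss_add) / mse_full
        F_b_full = (rss_a - rss_add) / mse_full
        F_a_add = (rss_b - rss_add) / mse_add
        F_b_add = (rss_a - rss_add) / mse_add
    keep = p_int < drop_interaction_at
    F_a = np.where(keep, F_a_full, F_a_add)
    F_b = np.where(keep, F_b_full, F_b_add)
    df_den = np.where(keep, df_full, df_add)
    p_a = stats.f.sf(F_a, 1, df_den)
    p_b = stats.f.sf(F_b, 1, df_den)
    return (F_a, p_a), (F_b, p_b), p_int


def anova_per_slice(
    cohort,
    eye_side: str | None = "OD",
    factors: tuple = ("sex", "origin"),
    drop_interaction_at: float = ANOVA_INTERACTION_DROP,
    m_tests: int = 9,
) -> AnovaTable:
    """Nine univariate two-factor ANOVAs (one per slice), Type II SS.

    Each slice is modelled on sex, origin and their interaction; the
    interaction is removed when its p-value is at or above
    ``drop_interaction_at`` and the additive model refitted. Significance
    stars divide the usual levels by ``m_tests`` (Bonferroni over the nine
    slice tests). All nine responses share one design, so the Type II sums
    of squares are computed in a single batched QR pass (equivalent to
    statsmodels ``anova_lm(typ=2)``, which serves as the cross-check
    oracle in the test suite).
    """
    df = _known_origin(_eye_filter(_as_df(cohort), eye_side))
    _check_factors(df, factors)
    fa, fb = factors
    Y = df[list(SLICE_NAMES)].to_numpy(dtype=float)
    a = (df[fa] == sorted(df[fa].unique())[1]).to_numpy()
    b = (df[fb] == sorted(df[fb].unique())[1]).to_numpy()
    (F_a, p_a), (F_b, p_b), p_int = _type2_two_factor(
        Y, a, b, drop_interaction_at
    )
    cells: dict = {}
    inter_p: dict = {}
    per_factor = {fa: (F_a, p_a), fb: (F_b, p_b)}
    for j, s in enumerate(SLICE_NAMES):
        inter_p[s] = float(p_int[j])
        for f in factors:
            F, p = per_factor[f]
            cells[(s, f)] = {
                "F": float(F[j]),
                "p": float(p[j]),
                "stars": bonferroni_stars(float(p[j]), m_tests),
            }
    return AnovaTable(
        cells=cells, interaction_p=inter_p, eye_side=eye_side, n_records=len(df)
    )


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------

@dataclass
class ReportBundle:
    """Machine-readable analogue of the reference-database result tables."""

    summary_tables: dict  # family -> DataFrame (grouped summaries)
    overall_central: SummaryStats | None
    correlation: CorrelationBlockSummary | None
    pca: dict  # eye side -> PcaResult
    manova: dict  # eye side -> ManovaResult
    anova: dict  # eye side -> AnovaTable
    unavailable: dict = field(default_factory=dict)  # section -> reason


_FAMILIES = {
    "zones": ZONE_NAMES,
    "quadrants": QUADRANT_NAMES,
    "slices": SLICE_NAMES,
}


def _grouped_summary_table(df: pd.DataFrame, regions) -> pd.DataFrame:
    """Rows: (eye, statistic); columns: (region, subgroup) with m/M-style codes."""
    stats_order = ["count", "mean", "std", "min", "median", "max", "cv"]
    cols = {}
    for region in regions:
        groups = {"All": df}
        if {"sex", "origin"}.issubset(df.columns):
            for (sex, origin), sub in df.groupby(["sex", "origin"], observed=True):
                code = f"{sex[0]}/{'M' if origin == 'Mauritius' else 'A' if origin == 'Asia' else 'U'}"
                groups[code] = sub
        for code, sub in groups.items():
            for eye in ("OD", "OS"):
                v = sub[sub["eye"] == eye][region]
                if len(v) == 0:
                    continue
                ss = SummaryStats.from_values(v)
                for stat in stats_order:
                    cols.setdefault((region, code), {})[(eye, stat)] = getattr(
                        ss, stat
                    )
    out = pd.DataFrame(cols)
    out.index = pd.MultiIndex.from_tuples(out.index, names=["eye", "stat"])
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["region", "group"])
    return out.sort_index()


def reproduce_report(
    cohort,
    outdir: str | Path | None = None,
    make_figures: bool = False,
) -> ReportBundle:
    """Compute the full reference-database report from a cohort.

    Emits grouped summary tables for zones/quadrants/slices, the
    correlation block summary, per-side PCA (first three PCs), per-side
    MANOVA and per-slice ANOVA tables, and optional grouped boxplot
    figures. Sections whose prerequisites are missing (metadata columns,
    factor levels, sample size) are marked unavailable instead of failing.
    """
    df = _as_df(cohort)
    unavailable: dict = {}
    bundle = ReportBundle(
        summary_tables={},
        overall_central=None,
        correlation=None,
        pca={},
        manova={},
        anova={},
        unavailable=unavailable,
    )
    bundle.overall_central = SummaryStats.from_values(df["Z1"]) if len(df) else None
    for family, regions in _FAMILIES.items():
        try:
            bundle.summary_tables[family] = _grouped_summary_table(df, regions)
        except Exception as exc:
            unavailable[f"summary_{family}"] = str(exc)
    try:
        bundle.correlation = correlation_block_summary(df)
    except Exception as exc:
        unavailable["correlation"] = str(exc)
    for side in ("OD", "OS"):
        try:
            bundle.pca[side] = pca_slices(df, side)
        except Exception as exc:
            unavailable[f"pca_{side}"] = str(exc)
        try:
            bundle.manova[side] = manova_slices(df, side)
        except Exception as exc:
            unavailable[f"manova_{side}"] = str(exc)
        try:
            bundle.anova[side] = anova_per_slice(df, side)
        except Exception as exc:
            unavailable[f"anova_{side}"] = str(exc)
    if outdir is not None:
        _write_bundle(bundle, df, Path(outdir), make_figures)
    return bundle


def _write_bundle(
    bundle: ReportBundle, df: pd.DataFrame, outdir: Path, make_figures: bool
) -> None:
    import json

    outdir.mkdir(parents=True, exist_ok=True)
    for family, table in bundle.summary_tables.items():
        table.to_csv(outdir / f"summary_{family}.csv")
    if bundle.correlation is not None:
        bundle.correlation.to_dataframe().to_csv(outdir / "correlation_blocks.csv")
    js: dict = {"unavailable": bundle.unavailable}
    if bundle.overall_central is not None:
        js["overall_central"] = vars(bundle.overall_central)
    for side, pca in bundle.pca.items():
        js[f"pca_{side}"] = {
            "explained_fraction": pca.explained_fraction.tolist(),
            "cumulative_fraction": pca.cumulative_fraction.tolist(),
        }
        pca.coefficients_table().to_csv(outdir / f"pca_coefficients_{side}.csv")
    for side, mv in bundle.manova.items():
        js[f"manova_{side}"] = {
            f: vars(t) for f, t in mv.factors.items()
        } | {"interaction_p": mv.interaction_p, "interaction_dropped": mv.interaction_dropped}
    for side, an in bundle.anova.items():
        an.stars_frame().to_csv(outdir / f"anova_stars_{side}.csv")
        js[f"anova_{side}"] = {
            f"{s}:{f}": cell for (s, f), cell in an.cells.items()
        }
    (outdir / "report.json").write_text(json.dumps(js, indent=2, default=float))
    if make_figures:
        _boxplot_figures(df, outdir)


def _boxplot_figures(df: pd.DataFrame, outdir: Path) -> None:
    """Grouped boxplots of each region family by sex/origin subgroup."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = df[df["origin"].isin(["Mauritius", "Asia"])].copy()
    if sub.empty or "sex" not in sub.columns:
        return
    sub["group"] = sub["sex"].str[0] + "/" + sub["origin"].str[0]
    for family, regions in _FAMILIES.items():
        fig, axes = plt.subplots(
            1, len(regions), figsize=(2.2 * len(regions), 3.2), sharey=False
        )
        for ax, region in zip(np.atleast_1d(axes), regions):
            groups = sorted(sub["group"].unique())
            ax.boxplot(
                [sub.loc[sub["group"] == g, region] for g in groups],
                tick_labels=groups,
            )
            ax.set_title(region)
            ax.tick_params(axis="x", rotation=90, labelsize=7)
        fig.suptitle(f"{family} volumes (mm³) by sex/origin")
        fig.tight_layout()
        fig.savefig(outdir / f"boxplot_{family}.svg")
        plt.close(fig)
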
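"""Cohort feature table, redundancy reduction and group comparison.

The analysis chain mirrors a two-group radiomics study:

1. per subject, quantize the VOI, accumulate one GLCM per distance and
   compute the 11 Haralick parameters — 55 variables (11 parameters x 5
   distances) per subject;
2. between-distance screening: each parameter's five distance columns are
   rank-correlated across subjects; when they carry the same ordering the
   table collapses to a single reference distance — the intermediate one
   (q3 for five distances);
3. between-parameter screening at the reference distance: representative
   selection — a parameter is excluded when it is very strongly rank-
   correlated (``|rho| >= threshold``, default 0.9, the conventional "very
   strong" boundary) with an already-retained one;
4. per retained parameter, an exact two-sided Mann-Whitney comparison of
   the AB and OKC groups with per-group position/dispersion summaries.

No multiple-testing adjustment is applied by default (raw p-values are
reported, with a Holm option behind a flag).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glcm import DEFAULT_DISTANCES, DEFAULT_N_LEVELS, QuantizationSpec, glcm_all_distances, quantize
from .haralick import DEFAULT_LOG_BASE, PARAMETER_NAMES, compute_features
from .io import VolumeWithMask, extract_voi

__all__ = [
    "build_feature_table",
    "feature_columns",
    "spearman_rho",
    "reduce_between_distances",
    "reduce_between_parameters",
    "reduce_redundancy",
    "mann_whitney",
    "compare_groups",
    "DistanceReduction",
    "Exclusion",
    "ReductionReport",
    "MannWhitneyResult",
    "ComparisonReport",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.9
DEFAULT_ALPHA = 0.05


def feature_columns(
    parameters: tuple[str, ...] = PARAMETER_NAMES,
    n_distances: int = len(DEFAULT_DISTANCES),
) -> list[str]:
    """Canonical column names ``parameter@q1 .. parameter@qK``."""
    return [f"{p}@q{d + 1}" for p in parameters for d in range(n_distances)]


def build_feature_table(
    cohort: list[VolumeWithMask],
    n_levels: int = DEFAULT_N_LEVELS,
    distances: tuple[int, ...] = DEFAULT_DISTANCES,
    log_base: str | float = DEFAULT_LOG_BASE,
) -> pd.DataFrame:
    """Subjects x (group + 55 variables) table.

    Index is subject_id; first column is the group label; remaining columns
    are the 11 parameters at each distance, in canonical order. Degenerate
    distances (no co-occurring pairs) yield NaN cells, logged per subject.
    """
    spec = QuantizationSpec(n_levels=n_levels)
    rows = {}
    groups = {}
    for vwm in cohort:
        try:
            qvoi = quantize(extract_voi(vwm), spec)
            glcms = glcm_all_distances(qvoi, distances)
        except Exception as exc:  # re-raise naming the subject
            raise type(exc)(f"subject {vwm.subject_id!r}: {exc}") from exc
        row: dict[str, float] = {}
        for d in glcms.distances:
            vec = compute_features(glcms.matrices[d], log_base=log_base)
            if vec.degenerate:
                logger.warning(
                    "subject %s: degenerate GLCM at distance %d (no pairs)",
                    vwm.subject_id,
                    d,
                )
            label = glcms.label(d)
            for name in PARAMETER_NAMES:
                row[f"{name}@{label}"] = vec[name]
        rows[vwm.subject_id] = row
        groups[vwm.subject_id] = vwm.group_label
    columns = feature_columns(PARAMETER_NAMES, len(distances))
    table = pd.DataFrame.from_dict(rows, orient="index")[columns]
    table.insert(0, "group", pd.Series(groups))
    table.index.name = "subject_id"
    return table


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with mid-ranks for ties.

    Returns NaN when either vector is constant (undefined).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def _distance_labels(table: pd.DataFrame) -> list[str]:
    labels = []
    for col in table.columns:
        if "@" in col:
            lab = col.split("@")[1]
            if lab not in labels:
                labels.append(lab)
    return labels


@dataclass
class DistanceReduction:
    """Step 1: between-distance rank correlation per parameter."""

    between_distance_rho: dict[str, pd.DataFrame]
    reference_distance: str
    failed: list[str]  # parameters whose min off-diagonal |rho| < threshold
    threshold: float


@dataclass
class Exclusion:
    parameter: str
    partner: str
    rho: float


@dataclass
class ReductionReport:
    """Outcome of the two-step redundancy reduction."""

    between_distance_rho: dict[str, pd.DataFrame]
    reference_distance: str
    within_distance_rho: pd.DataFrame
    excluded: list[Exclusion]
    retained: list[str]
    threshold: float
    distance_failures: list[str] = field(default_factory=list)

    @property
    def excluded_names(self) -> list[str]:
        return [e.parameter for e in self.excluded]

    def to_dict(self) -> dict:
        return {
            "reference_distance": self.reference_distance,
            "threshold": self.threshold,
            "retained": self.retained,
            "excluded": [
                {"parameter": e.parameter, "partner": e.partner, "rho": e.rho}
                for e in self.excluded
            ],
            "between_distance_failures": self.distance_failures,
        }


def reduce_between_distances(
    ft: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    reference: str | None = None,
) -> DistanceReduction:
    """Screen each parameter's distance columns for rank-equivalence.

    When every parameter's five distance columns are pairwise
    ``|rho| >= threshold`` they carry the same ordering and a single
    distance suffices; the intermediate one is taken as reference
    (configurable). Parameters falling short are flagged, not fatal — the
    collapse still happens at the configured reference.
    """
    if len(ft) < 3:
        raise ValueError("need at least 3 subjects for rank correlation")
    labels = _distance_labels(ft)
    if reference is None:
        reference = labels[len(labels) // 2]  # middle distance, e.g. q3 of 5
    if reference not in labels:
        raise ValueError(f"reference {reference!r} not among distances {labels}")
    rho_by_param: dict[str, pd.DataFrame] = {}
    failed: list[str] = []
    for param in PARAMETER_NAMES:
        cols = [f"{param}@{lab}" for lab in labels if f"{param}@{lab}" in ft.columns]
        if len(cols) < 2:
            continue
        sub = ft[cols].dropna()
        mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
        for a, b in itertools.combinations(cols, 2):
            r = spearman_rho(sub[a], sub[b])
            mat.loc[a, b] = mat.loc[b, a] = r
        rho_by_param[param] = mat
        off = mat.values[~np.eye(len(cols), dtype=bool)]
        if np.any(np.isnan(off)) or np.min(np.abs(off)) < threshold:
            failed.append(param)
    return DistanceReduction(
        between_distance_rho=rho_by_param,
        reference_distance=reference,
        failed=failed,
        threshold=threshold,
    )


def _spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    cols = list(table.columns)
    mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        sub = table[[a, b]].dropna()
        r = spearman_rho(sub[a], sub[b]) if len(sub) >= 3 else float("nan")
        mat.loc[a, b] = mat.loc[b, a] = r
    return mat


#: Parameters computed from the joint gray-level pair distribution (or its
#: primary row marginal). Statistics of the derived sum/difference marginals
#: carry no independent information — for a symmetric GLCM the sum variance
#: is exactly ``2*variance*(1+correlation)``, and the sum/difference
#: entropies are bounded by the joint entropy — so when a redundant pair
#: spans the two groups the joint-distribution statistic is the natural
#: representative to retain.
JOINT_PARAMETERS = frozenset(
    {"contrast", "correlation", "entropy", "homogeneity", "uniformity", "variance"}
)


def reduce_between_parameters(
    ft_at_ref: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> ReductionReport:
    """Step 2: representative selection among rank-redundant parameters.

    Parameters are visited joint-distribution statistics first (see
    :data:`JOINT_PARAMETERS`), each group in descending order of centrality
    (mean ``|rho|`` against the other ten; alphabetical tie-break). Each is
    kept unless it is very strongly correlated (``|rho| >= threshold``)
    with a parameter already kept, in which case it is excluded and its
    strongest kept partner recorded. A redundant cluster is thus
    represented by its primary, most central member, and every exclusion
    has an explicit retained partner. Deterministic given the table.
    """
    if len(ft_at_ref) < 3:
        raise ValueError("need at least 3 subjects for rank correlation")
    ft_at_ref = ft_at_ref.copy()
    ft_at_ref.columns = [c.split("@")[0] for c in ft_at_ref.columns]
    rho = _spearman_matrix(ft_at_ref)
    names = list(ft_at_ref.columns)
    mean_abs = {}
    for name in names:
        others = [o for o in names if o != name]
        vals = np.abs(rho.loc[name, others].values.astype(float))
        mean_abs[name] = float(np.nansum(vals) / max(len(others), 1))
    order = sorted(names, key=lambda n: (n not in JOINT_PARAMETERS, -mean_abs[n], n))
    kept: list[str] = []
    excluded: list[Exclusion] = []
    for name in order:
        # redundancy is transitive: a parameter whose information is already
        # carried by an excluded parameter is itself covered by that
        # parameter's retained representative
        decided = kept + [e.parameter for e in excluded]
        links = {
            k: abs(float(rho.loc[name, k]))
            for k in decided
            if np.isfinite(rho.loc[name, k])
        }
        partner = max(links, key=links.get) if links else None
        if partner is not None and links[partner] >= threshold:
            excluded.append(
                Exclusion(
                    parameter=name,
                    partner=partner,
                    rho=float(rho.loc[name, partner]),
                )
            )
        else:
            kept.append(name)
    retained = [n for n in names if n in kept]
    return ReductionReport(
        between_distance_rho={},
        reference_distance="",
        within_distance_rho=rho,
        excluded=excluded,
        retained=retained,
        threshold=threshold,
    )


def reduce_redundancy(
    ft: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    reference: str | None = None,
) -> ReductionReport:
    """Both reduction steps on a full feature table."""
    step1 = reduce_between_distances(ft, threshold=threshold, reference=reference)
    ref = step1.reference_distance
    cols = [f"{p}@{ref}" for p in PARAMETER_NAMES if f"{p}@{ref}" in ft.columns]
    report = reduce_between_parameters(ft[cols], threshold=threshold)
    report.between_distance_rho = step1.between_distance_rho
    report.reference_distance = ref
    report.distance_failures = step1.failed
    return report


@dataclass
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # "exact" or "asymptotic"


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration of the null distribution of U when the
    combined sample is small (``n1 + n2 <= 20``) and tie-free; otherwise a
    mid-rank U with tie-corrected normal approximation (no continuity
    correction, so exchangeable samples give p = 1).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    if len(x) + len(y) < 4:
        raise ValueError("combined sample must have at least 4 observations")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 20 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        method = "asymptotic"
    return MannWhitneyResult(
        u=float(res.statistic), p_value=min(float(res.pvalue), 1.0), method=method
    )


@dataclass
class ComparisonReport:
    """Per-parameter group summaries and Mann-Whitney p-values.

    ``table`` has one row per (parameter, group) with columns parameter,
    group, n, mean, sd, median, p_value, significant, method — the median is
    the position measure reported alongside the mean.
    """

    table: pd.DataFrame
    alpha: float
    reference_distance: str

    def to_markdown(self) -> str:
        lines = [
            "| Parameter | Group | N | Mean | S.D. | Median | p-value |",
            "|---|---|---|---|---|---|---|",
        ]
        for param, sub in self.table.groupby("parameter", sort=False):
            for pos, (_, r) in enumerate(sub.iterrows()):
                star = " *" if r["significant"] and pos == 0 else ""
                pv = f"{r['p_value']:.3g}{star}" if pos == 0 else ""
                lines.append(
                    f"| {param if pos == 0 else ''} | {r['group']} | {r['n']} "
                    f"| {r['mean']:.4g} | {r['sd']:.4g} | {r['median']:.4g} | {pv} |"
                )
        return "\n".join(lines) + "\n"


def compare_groups(
    ft: pd.DataFrame,
    reduction: ReductionReport,
    alpha: float = DEFAULT_ALPHA,
    holm: bool = False,
) -> ComparisonReport:
    """Mann-Whitney comparison of the two groups per retained parameter.

    Works at the reduction's reference distance; missing cells are dropped
    pairwise with a logged count. Raw p-values by default (``holm=True``
    applies a Holm step-down adjustment before flagging).
    """
    if "group" not in ft.columns:
        raise ValueError("feature table lacks a 'group' column")
    groups = [g for g in ("AB", "OKC") if (ft["group"] == g).any()]
    if len(groups) < 2:
        raise ValueError("need both AB and OKC subjects for comparison")
    if min((ft["group"] == g).sum() for g in groups) < 2:
        raise ValueError("need at least 2 subjects per group")
    ref = reduction.reference_distance
    rows = []
    pvals = []
    for param in reduction.retained:
        col = f"{param}@{ref}"
        sub = ft[["group", col]].dropna()
        n_dropped = len(ft) - len(sub)
        if n_dropped:
            logger.info("%s: dropped %d subjects with missing values", col, n_dropped)
        x = sub.loc[sub["group"] == "AB", col].values
        y = sub.loc[sub["group"] == "OKC", col].values
        mw = mann_whitney(x, y)
        pvals.append(mw.p_value)
        for g, v in (("AB", x), ("OKC", y)):
            rows.append(
                {
                    "parameter": param,
                    "group": g,
                    "n": len(v),
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
                    "median": float(np.median(v)),
                    "p_value": mw.p_value,
                    "method": mw.method,
                }
            )
    pvals = np.array(pvals)
    if holm:
        order = np.argsort(pvals)
        adj = np.empty_like(pvals)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (len(pvals) - rank) * pvals[idx])
            adj[idx] = min(running, 1.0)
        flag_p = adj
    else:
        flag_p = pvals
    table = pd.DataFrame(rows)
    table["significant"] = np.repeat(flag_p <= alpha, 2)
    return ComparisonReport(table=table, alpha=alpha, reference_distance=ref)
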
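"""Group-association statistics for abundances, ratios, enterotypes and
ordination coordinates.

The test battery mirrors standard practice for two-arm microbiome cohorts:
two-tailed Mann-Whitney for responder vs non-responder abundance and ratio
contrasts, Kruskal-Wallis with post hoc Dunn tests (Bonferroni-adjusted)
across enterotypes, one-tailed two-proportion Z-tests (pooled variance, no
continuity correction) for responder proportions between enterotypes,
non-metric multidimensional scaling (NMDS, Kruskal stress-1, many random
restarts with a Procrustes convergence check) and two-sample t-tests on the
NMDS coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import procrustes as _procrustes
from sklearn.manifold import MDS as _MDS
from statsmodels.stats.proportion import proportions_ztest as _proportions_ztest

from .enterotype import _check_distance, pcoa


@dataclass
class AssociationReport:
    """One statistical comparison: test, statistic, p, group summaries."""

    test: str
    statistic: float
    p_value: float
    tail: str  # "one" or "two"
    groups: dict[str, dict[str, float]] = field(default_factory=dict)
    adjustment: str | None = None
    adjusted_p: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "tail": self.tail,
            "groups": self.groups,
        }
        if self.adjustment is not None:
            out["adjustment"] = self.adjustment
            out["adjusted_p"] = self.adjusted_p
        if self.extra:
            out.update(self.extra)
        return out


@dataclass
class NmdsSolution:
    coordinates: pd.DataFrame  # samples x dims
    stress: float  # Kruskal stress-1
    n_restarts_used: int
    converged: bool


def _summaries(named: dict[str, np.ndarray]) -> dict[str, dict[str, float]]:
    return {
        name: {
            "n": int(len(v)),
            "median": float(np.median(v)) if len(v) else float("nan"),
            "mean": float(np.mean(v)) if len(v) else float("nan"),
        }
        for name, v in named.items()
    }


def mann_whitney(
    x, y, x_name: str = "x", y_name: str = "y"
) -> AssociationReport:
    """Two-tailed Mann-Whitney U test.

    Exact enumeration when both groups have at most 8 untied values;
    otherwise the normal approximation with midrank tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return AssociationReport(
        test="mann-whitney",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        tail="two",
        groups=_summaries({x_name: x, y_name: y}),
        extra={"method": method},
    )


def kruskal_wallis(groups: list, names: list[str] | None = None) -> AssociationReport:
    """Kruskal-Wallis H test (tie-corrected, chi-square p)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(arrays)
    if len(np.unique(pooled)) < 2:
        raise ValueError("all values identical: Kruskal-Wallis undefined")
    res = stats.kruskal(*arrays)
    names = names or [f"group{i + 1}" for i in range(len(arrays))]
    return AssociationReport(
        test="kruskal-wallis",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        tail="two",
        groups=_summaries(dict(zip(names, arrays))),
        extra={"df": len(arrays) - 1},
    )


def dunn_posthoc(
    groups: list, names: list[str] | None = None
) -> list[AssociationReport]:
    """Dunn's post hoc pairwise tests after Kruskal-Wallis.

    Pairwise z statistics from pooled midranks with tie correction; raw
    two-sided normal p values; Bonferroni family-wise adjustment
    (adjusted p = min(1, p x number of pairs)).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    kruskal_wallis(arrays)  # validates applicability
    names = names or [f"group{i + 1}" for i in range(len(arrays))]
    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    # tie correction term: sum(t^3 - t) / (12 (N - 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    mean_ranks, sizes = [], []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start:start + len(a)].mean())
        sizes.append(len(a))
        start += len(a)
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    reports = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            se = np.sqrt(
                (N * (N + 1) / 12.0 - tie_term)
                * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = float(2.0 * stats.norm.sf(abs(z)))
            reports.append(
                AssociationReport(
                    test="dunn",
                    statistic=float(z),
                    p_value=p,
                    tail="two",
                    groups=_summaries(
                        {names[i]: arrays[i], names[j]: arrays[j]}
                    ),
                    adjustment="bonferroni",
                    adjusted_p=float(min(1.0, p * n_pairs)),
                    extra={"pair": (names[i], names[j])},
                )
            )
    return reports


def two_proportion_ztest(
    x1: int, n1: int, x2: int, n2: int, tail: str = "one"
) -> AssociationReport:
    """Two-proportion Z-test with pooled variance, no continuity correction.

    ``tail="one"`` tests p1 > p2; ``tail="two"`` is two-sided.  A degenerate
    pooled proportion (0 or 1) yields p = 1 with a warning.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 <= 0 or n2 <= 0:
        raise ValueError("need 0 <= successes <= totals and positive totals")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    pooled = (x1 + x2) / (n1 + n2)
    groups = {
        "group1": {"n": n1, "successes": x1, "proportion": x1 / n1},
        "group2": {"n": n2, "successes": x2, "proportion": x2 / n2},
    }
    if pooled in (0.0, 1.0):
        warnings.warn(
            "degenerate pooled proportion; test uninformative", stacklevel=2
        )
        return AssociationReport(
            test="two-proportion-z", statistic=0.0, p_value=1.0,
            tail=tail, groups=groups, extra={"degenerate": True},
        )
    alternative = "larger" if tail == "one" else "two-sided"
    z, p = _proportions_ztest([x1, x2], [n1, n2], alternative=alternative)
    return AssociationReport(
        test="two-proportion-z", statistic=float(z), p_value=float(p),
        tail=tail, groups=groups,
    )


def axis_ttest(
    coords: pd.Series, groups: pd.Series,
    group_names: tuple[str, str] | None = None,
) -> AssociationReport:
    """Two-tailed two-sample t-test (pooled variance) on one ordination axis."""
    groups = groups.reindex(coords.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    levels = list(group_names) if group_names else sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    a = coords[groups == levels[0]].to_numpy(dtype=float)
    b = coords[groups == levels[1]].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two samples")
    res = stats.ttest_ind(a, b, equal_var=True)
    return AssociationReport(
        test="t-test", statistic=float(res.statistic),
        p_value=float(res.pvalue), tail="two",
        groups=_summaries({levels[0]: a, levels[1]: b}),
    )


# ---------------------------------------------------------------------------
# NMDS


def nmds(
    dist: pd.DataFrame,
    dims: int = 2,
    n_restarts: int = 1000,
    seed: int = 0,
    procrustes_tol: float = 1e-4,
    max_iter: int = 300,
    eps: float = 1e-7,
) -> NmdsSolution:
    """Non-metric multidimensional scaling with multiple restarts.

    Each restart minimizes Kruskal stress-1 by SMACOF with isotonic
    regression of fitted on observed dissimilarities.  The first restart is
    initialized from PCoA coordinates, the remainder from random Gaussian
    configurations.  The best (lowest-stress) solution is kept; restarts
    stop early once the Procrustes RMSE between the two best solutions
    (after scaling to unit total variance) falls below ``procrustes_tol``,
    i.e. independent starts have converged on the same configuration.
    """
    arr = _check_distance(dist)
    n = arr.shape[0]
    if dims >= n - 1:
        raise ValueError(f"dims ({dims}) must be < n_samples - 1 ({n - 1})")
    if n < dims + 2:
        raise ValueError("too few samples for the requested dimension")
    rng = np.random.default_rng(seed)

    def one_fit(init: np.ndarray) -> tuple[np.ndarray, float]:
        model = _MDS(
            n_components=dims, metric_mds=False, metric="precomputed",
            n_init=1, init="random", max_iter=max_iter, eps=eps,
            normalized_stress=True, random_state=0,
        )
        coords = model.fit_transform(arr, init=init)
        return coords, float(model.stress_)

    solutions: list[tuple[float, np.ndarray]] = []
    try:
        init0 = pcoa(dist, n_axes=dims).coordinates.to_numpy()
        if init0.shape[1] < dims:  # pad if PCoA yielded fewer positive axes
            pad = rng.normal(size=(n, dims - init0.shape[1])) * 1e-3
            init0 = np.hstack([init0, pad])
    except Exception:
        init0 = rng.normal(size=(n, dims))

    converged = False
    used = 0
    for r in range(n_restarts):
        init = init0 if r == 0 else rng.normal(size=(n, dims))
        coords, stress = one_fit(init)
        solutions.append((stress, coords))
        used = r + 1
        if len(solutions) >= 2:
            best2 = sorted(solutions, key=lambda s: s[0])[:2]
            try:
                m1, m2, disparity = _procrustes(best2[0][1], best2[1][1])
                rmse = float(np.sqrt(disparity / n))
            except ValueError:
                continue
            if rmse < procrustes_tol:
                converged = True
                break

    best_stress, best_coords = min(solutions, key=lambda s: s[0])
    cols = [f"NMDS{i + 1}" for i in range(dims)]
    return NmdsSolution(
        coordinates=pd.DataFrame(best_coords, index=dist.index, columns=cols),
        stress=best_stress,
        n_restarts_used=used,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# suite


def run_association_suite(
    *,
    gene_cpm: pd.DataFrame,
    gene_ko: pd.Series,
    category_abundance: pd.DataFrame,
    ratios: dict[str, pd.Series],
    metadata: pd.DataFrame,
    enterotype_assignments: pd.Series | None = None,
    nmds_solution: NmdsSolution | None = None,
    lps_gene_names: tuple[str, ...] = ("lpxL", "lpxJ", "lpxM"),
) -> dict[str, AssociationReport | list[AssociationReport]]:
    """Run the full per-figure association battery on one cohort.

    Emits, keyed by analysis name: responder vs non-responder Mann-Whitney
    tests on total LPS gene abundance, each late acyltransferase gene, each
    LPS taxon category and each ratio series (zero-value samples excluded
    first); per-enterotype Kruskal-Wallis + Dunn tests and pairwise
    responder-proportion Z-tests when an enterotype fit is supplied; and
    t-tests on NMDS axes when an ordination is supplied.
    """
    from .quantify import nonzero_subset  # deferred: avoids import cycle

    if "response" not in metadata.columns:
        raise ValueError("metadata must carry a 'response' column")
    response = metadata["response"]
    r_mask = response == "R"
    nr_mask = response == "NR"
    if not r_mask.any() or not nr_mask.any():
        raise ValueError("both responder and non-responder samples required")

    def mw_by_response(series: pd.Series, exclude_zeros: bool = True):
        s = series.dropna()
        if exclude_zeros:
            s, _ = nonzero_subset(s)
        grp = response.reindex(s.index)
        return mann_whitney(
            s[grp == "R"], s[grp == "NR"], x_name="R", y_name="NR"
        )

    out: dict = {}

    ko_totals = gene_cpm.groupby(gene_ko).sum()  # KO x samples
    lps_total = ko_totals.sum(axis=0)
    out["total_lps_genes_R_vs_NR"] = mw_by_response(lps_total)
    for gene in lps_gene_names:
        if gene in ko_totals.index:
            out[f"{gene}_R_vs_NR"] = mw_by_response(ko_totals.loc[gene])

    for cat in ("total_lps", "penta", "hexa_total"):
        if cat in category_abundance.columns:
            out[f"category_{cat}_R_vs_NR"] = mw_by_response(
                category_abundance[cat], exclude_zeros=False
            )
    for name, series in ratios.items():
        out[f"ratio_{name}_R_vs_NR"] = mw_by_response(
            series, exclude_zeros=False
        )

    if enterotype_assignments is not None:
        ent = enterotype_assignments.reindex(metadata.index)
        levels = sorted(ent.dropna().unique())
        groups = [lps_total.reindex(ent.index[ent == lv]).dropna() for lv in levels]
        names = [f"E{lv}" for lv in levels]
        if len(levels) >= 2:
            out["enterotype_total_lps_kw"] = kruskal_wallis(groups, names)
            out["enterotype_total_lps_dunn"] = dunn_posthoc(groups, names)
            if "lpxM" in ko_totals.index:
                g2 = [
                    ko_totals.loc["lpxM"].reindex(ent.index[ent == lv]).dropna()
                    for lv in levels
                ]
                out["enterotype_lpxM_kw"] = kruskal_wallis(g2, names)
                out["enterotype_lpxM_dunn"] = dunn_posthoc(g2, names)
            ztests = []
            for i in range(len(levels)):
                for j in range(i + 1, len(levels)):
                    mi = ent == levels[i]
                    mj = ent == levels[j]
                    ztests.append(
                        two_proportion_ztest(
                            int((r_mask & mi).sum()), int(mi.sum()),
                            int((r_mask & mj).sum()), int(mj.sum()),
                            tail="one",
                        )
                    )
            out["enterotype_responder_proportions"] = ztests

    if nmds_solution is not None:
        for axis in nmds_solution.coordinates.columns:
            out[f"nmds_{axis}_ttest"] = axis_ttest(
                nmds_solution.coordinates[axis], response,
                group_names=("R", "NR"),
            )
    return out
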
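"""Hypothesis tests and summaries behind the chromatin-signature analyses.

All group comparisons are nonparametric unpaired Mann-Whitney-Wilcoxon tests;
significance is reported in the categories used throughout the study
(p < 0.01 "strong", 0.01 <= p < 0.05 plain, otherwise ns), with the direction
taken from the sign of the median treated-minus-untreated difference. No
false-discovery-rate procedure is applied anywhere; the only multiple-testing
correction is a Bonferroni factor on the 3D-compartment hypergeometric tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MAX_N = 20  # combined sample size up to which the exact null is enumerated

_ALTERNATIVES = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


def wilcoxon_two_sample(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> float:
    """Unpaired Mann-Whitney-Wilcoxon p-value for samples ``x`` vs ``y``.

    Uses the exact permutation null when the combined size is at most 20 and
    the data are tie-free; otherwise the normal approximation with tie and
    continuity corrections. ``alternative='less'`` tests whether ``x`` is
    stochastically smaller than ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    combined = np.concatenate([x, y])
    ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= EXACT_MAX_N and not ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=_ALTERNATIVES[alternative], method=method,
        use_continuity=True,
    )
    return float(res.pvalue)


def significance_category(p: float, direction: str) -> str:
    """Map a p-value and change direction onto the study's colour categories."""
    if not (0 <= p <= 1):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if direction not in ("increase", "decrease", "none"):
        raise ValueError(f"unknown direction {direction!r}")
    if direction == "none" or p >= 0.05:
        return "ns"
    prefix = "strong_" if p < 0.01 else ""
    return f"{prefix}{direction}"


@dataclass
class SignatureResult:
    """Outcome of one damage-change test for a feature at one window size."""

    feature: str
    window_bp: int
    group: str  # all_DSB | random | HR | NHEJ
    p_value: float
    direction: str
    category: str

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError("p_value outside [0, 1]")
        if self.category != significance_category(self.p_value, self.direction):
            raise ValueError("category inconsistent with (p_value, direction)")


def damage_change_test(
    treated: Sequence[float],
    untreated: Sequence[float],
    feature: str,
    window_bp: int,
    group: str = "all_DSB",
    alternative: str = "two_sided",
) -> SignatureResult:
    """Compare per-site window counts between damaged and undamaged conditions.

    Direction comes from the sign of median(treated) - median(untreated);
    a zero median difference forces direction "none" and category ns.
    """
    treated = np.asarray(treated, dtype=float)
    untreated = np.asarray(untreated, dtype=float)
    if len(treated) == 0 or len(untreated) == 0:
        raise ValueError("site subset is empty")
    p = wilcoxon_two_sample(treated, untreated, alternative=alternative)
    diff = float(np.median(treated) - np.median(untreated))
    direction = "increase" if diff > 0 else ("decrease" if diff < 0 else "none")
    return SignatureResult(
        feature=feature,
        window_bp=window_bp,
        group=group,
        p_value=p,
        direction=direction,
        category=significance_category(p, direction),
    )


def multiscale_compare(
    hr_counts: Mapping[int, pd.DataFrame],
    nhej_counts: Mapping[int, pd.DataFrame],
) -> pd.DataFrame:
    """Two-sided tests of HR vs NHEJ per-site counts across window sizes.

    ``hr_counts[window]`` and ``nhej_counts[window]`` are sites x features
    frames sharing columns. Returns a features x windows frame of p-values.
    """
    windows = sorted(hr_counts)
    if windows != sorted(nhej_counts):
        raise ValueError("window sets differ between groups")
    if len(windows) < 2:
        raise ValueError("need at least 2 window sizes")
    features = list(hr_counts[windows[0]].columns)
    out = pd.DataFrame(index=features, columns=windows, dtype=float)
    for w in windows:
        hr = hr_counts[w]
        nj = nhej_counts[w]
        if list(hr.columns) != features or list(nj.columns) != features:
            raise ValueError("feature columns differ across windows/groups")
        if len(hr) < 2 or len(nj) < 2:
            raise ValueError("each group needs at least 2 sites")
        for f in features:
            out.loc[f, w] = wilcoxon_two_sample(
                hr[f].to_numpy(), nj[f].to_numpy(), "two_sided"
            )
    out.index.name = "feature"
    out.columns.name = "window_bp"
    return out


def basal_group_enrichment(
    hr_counts: pd.DataFrame,
    nhej_counts: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.Series:
    """Label features enriched at HR or NHEJ sites before damage.

    Runs both one-sided tests per feature on undamaged-condition counts and
    assigns the significant direction; ns when neither one-sided p is below
    ``alpha``. Both directions significant at once is impossible for the two
    one-sided tests on the same data and is asserted.
    """
    if len(hr_counts) == 0 or len(nhej_counts) == 0:
        raise ValueError("groups must be non-empty")
    labels = {}
    for f in hr_counts.columns:
        x = hr_counts[f].to_numpy()
        y = nhej_counts[f].to_numpy()
        p_hr = wilcoxon_two_sample(x, y, "greater")
        p_nhej = wilcoxon_two_sample(x, y, "less")
        assert not (p_hr < alpha and p_nhej < alpha)
        if p_hr < alpha:
            labels[f] = "HR_enriched"
        elif p_nhej < alpha:
            labels[f] = "NHEJ_enriched"
        else:
            labels[f] = "ns"
    return pd.Series(labels, name="basal_enrichment")


def spearman_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rank correlations across features (columns).

    Average ranks resolve ties; a constant column yields NaN against every
    other feature (undefined correlation) but keeps 1 on the diagonal.
    """
    if len(counts) < 3:
        raise ValueError("need at least 3 sites")
    features = list(counts.columns)
    out = pd.DataFrame(np.eye(len(features)), index=features, columns=features)
    for i, a in enumerate(features):
        for j in range(i + 1, len(features)):
            b = features[j]
            xa = counts[a].to_numpy(float)
            xb = counts[b].to_numpy(float)
            if np.all(xa == xa[0]) or np.all(xb == xb[0]):
                rho = np.nan
            else:
                rho = sps.spearmanr(xa, xb).statistic
            out.loc[a, b] = rho
            out.loc[b, a] = rho
    return out


@dataclass
class CompartmentEnrichment:
    """Hypergeometric enrichment of one break category in one 3D compartment."""

    category: str  # HR | NHEJ
    compartment: str
    observed: int
    pool_size: int
    category_size: int
    draws: int
    direction: str  # enriched | depleted
    p_raw: float
    p_bonferroni: float


def compartment_enrichment(
    loop_labels: Mapping[str, str],
    hr_loops: Sequence[str],
    nhej_loops: Sequence[str],
) -> list[CompartmentEnrichment]:
    """Test whether HR/NHEJ loops distribute among compartments like all loops.

    For each compartment and category the enrichment p-value is the upper
    hypergeometric tail P(X >= observed) and the depletion p-value the lower
    tail P(X <= observed), drawing ``len(category)`` loops from the labelled
    pool. Bonferroni factor = n_compartments x 2 directions x 2 categories.
    """
    for name, loops in (("HR", hr_loops), ("NHEJ", nhej_loops)):
        missing = [l for l in loops if l not in loop_labels]
        if missing:
            raise KeyError(f"{name} loops absent from labels: {missing[:5]}")
    pool_size = len(loop_labels)
    compartments = sorted(set(loop_labels.values()))
    n_tests = len(compartments) * 2 * 2
    results: list[CompartmentEnrichment] = []
    for category, loops in (("HR", hr_loops), ("NHEJ", nhej_loops)):
        draws = len(loops)
        for comp in compartments:
            k_comp = sum(1 for v in loop_labels.values() if v == comp)
            observed = sum(1 for l in loops if loop_labels[l] == comp)
            dist = sps.hypergeom(pool_size, k_comp, draws)
            p_enr = float(dist.sf(observed - 1))
            p_dep = float(dist.cdf(observed))
            for direction, p_raw in (("enriched", p_enr), ("depleted", p_dep)):
                p_raw = min(1.0, p_raw)
                results.append(
                    CompartmentEnrichment(
                        category=category,
                        compartment=comp,
                        observed=observed,
                        pool_size=pool_size,
                        category_size=k_comp,
                        draws=draws,
                        direction=direction,
                        p_raw=p_raw,
                        p_bonferroni=min(1.0, p_raw * n_tests),
                    )
                )
    return results


def compartment_enrichment_frame(
    results: Sequence[CompartmentEnrichment],
) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
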
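"""Expression statistics: fold changes, the unique expression factor (UEF),
its significance, ortholog-profile clustering and cross-strain FC correlation.

The UEF of a TSS is the fold change between its maximal condition and the
condition with the second-highest read count; values above 5 indicate
strong condition-specific induction. The published decision rule for a
significant UEF — |FC| >= 2 and p(|FC| >= 2) >= 0.95 — is kept verbatim;
the probability itself comes from a conjugate Gamma–Poisson model on the
raw counts (Jeffreys Gamma(1/2) prior on each rate), under which the
posterior rate ratio reduces to a scaled Beta variable and the tail mass
has a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .model import CONDITIONS, Thresholds

__all__ = [
    "UEFResult",
    "fold_change",
    "uef",
    "uef_significance",
    "significant_uef",
    "cluster_ortholog_profiles",
    "pairwise_fc_correlation",
]


@dataclass
class UEFResult:
    tu_id: str
    uef: float
    top_condition: Optional[str]
    second_condition: Optional[str]
    high: bool = False
    significant: Optional[bool] = None
    posterior: Optional[float] = None
    undefined: bool = False


def fold_change(a: float, b: float, pseudocount: float = 1.0) -> float:
    """(a + pc) / (b + pc) on normalized counts; infinite when pc = 0, b = 0."""
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    if b + pseudocount == 0:
        return float("inf") if a > 0 else float("nan")
    return (a + pseudocount) / (b + pseudocount)


def uef(counts, pseudocount: float = 1.0, tu_id: str = "",
        th: Thresholds | None = None) -> UEFResult:
    """Unique expression factor: max over second-max after pseudocounting.

    An all-zero vector has no defined UEF and is flagged; two tied maxima
    give UEF = 1 (no condition is unique).
    """
    th = th or Thresholds()
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValueError("UEF needs a vector of >=2 condition counts")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if not np.any(counts > 0):
        return UEFResult(tu_id, float("nan"), None, None, undefined=True)
    order = np.argsort(-counts, kind="stable")
    top, second = order[0], order[1]
    value = fold_change(counts[top], counts[second], pseudocount)
    labels = CONDITIONS if len(counts) == len(CONDITIONS) else tuple(str(i) for i in range(len(counts)))
    return UEFResult(
        tu_id=tu_id,
        uef=value,
        top_condition=labels[top],
        second_condition=labels[second],
        high=bool(value > th.uef_high),
    )


def uef_significance(raw_a: int, raw_b: int, exposure_a: float = 1.0,
                     exposure_b: float = 1.0, fc_threshold: float = 2.0) -> float:
    """Posterior probability that the rate ratio differs >= fc_threshold-fold.

    Raw (unscaled, integer) counts a and b are modelled as Poisson with
    rates lambda_a * exposure_a and lambda_b * exposure_b under independent
    Jeffreys Gamma(1/2, eps -> 0) priors. The posterior of
    R = lambda_a / lambda_b is then a scaled ratio of Gammas, and
    P(R >= c or R <= 1/c) follows from the Beta distribution of
    G_a / (G_a + G_b).
    """
    for v in (raw_a, raw_b):
        if v != int(v) or v < 0:
            raise ValueError(f"raw counts must be non-negative integers, got {v}")
    if exposure_a <= 0 or exposure_b <= 0:
        raise ValueError("exposures must be positive")
    alpha_a = raw_a + 0.5
    alpha_b = raw_b + 0.5
    # R = (G_a / e_a) / (G_b / e_b); P(R >= c) = P(G_a/G_b >= c e_a/e_b)
    def tail_ge(c: float) -> float:
        t = c * exposure_a / exposure_b
        return float(stats.beta.sf(t / (1.0 + t), alpha_a, alpha_b))

    p_up = tail_ge(fc_threshold)
    p_down = 1.0 - tail_ge(1.0 / fc_threshold)
    return p_up + p_down


def significant_uef(raw_a: int, raw_b: int, exposure_a: float = 1.0,
                    exposure_b: float = 1.0, th: Thresholds | None = None) -> tuple[bool, float]:
    """Apply the decision rule: |FC| >= 2 on the exposure-adjusted rates AND
    posterior >= 0.95. Returns (significant, posterior)."""
    th = th or Thresholds()
    posterior = uef_significance(raw_a, raw_b, exposure_a, exposure_b, th.fc_min)
    rate_a = raw_a / exposure_a
    rate_b = raw_b / exposure_b
    if rate_b == 0 and rate_a == 0:
        fc = 1.0
    elif rate_b == 0 or rate_a == 0:
        fc = float("inf")
    else:
        fc = max(rate_a / rate_b, rate_b / rate_a)
    return bool(fc >= th.fc_min and posterior >= th.posterior_min), posterior


def _transform_profiles(x: np.ndarray) -> np.ndarray:
    """log2(x+1) then per-row z-score (constant rows map to zero)."""
    x = np.log2(np.asarray(x, dtype=float) + 1.0)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def cluster_ortholog_profiles(profiles_a: np.ndarray, profiles_b: np.ndarray,
                              k: int = 10, seed: int = 0) -> tuple[np.ndarray, np.ndarray, float]:
    """Joint k-means over both strains' ortholog expression profiles.

    Profiles are log2(x+1)-transformed and z-scored per TU, stacked into a
    single matrix, and clustered once (10 restarts, best inertia). Returns
    (labels_a, labels_b, same_cluster_fraction) where the fraction is the
    share of ortholog pairs whose two members land in the same cluster.
    """
    a = np.asarray(profiles_a, dtype=float)
    b = np.asarray(profiles_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("ortholog profile matrices must have matching shapes")
    n = a.shape[0]
    if k > 2 * n:
        raise ValueError(f"k={k} exceeds the number of profiles ({2 * n})")
    x = _transform_profiles(np.vstack([a, b]))
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(x)
    labels_a, labels_b = labels[:n], labels[n:]
    return labels_a, labels_b, float(np.mean(labels_a == labels_b))


def pairwise_fc_correlation(profiles_a: np.ndarray, profiles_b: np.ndarray,
                            pseudocount: float = 1.0) -> tuple[float, pd.DataFrame]:
    """R-squared between the strains' log2 fold changes over condition pairs.

    For every ortholog pair and each of the C(10,2) = 45 unordered
    condition pairs, the log2 FC is computed in both strains; the squared
    Pearson correlation over all points is returned together with the
    scatter table. Zero variance on either axis leaves R^2 undefined (NaN).
    """
    a = np.asarray(profiles_a, dtype=float)
    b = np.asarray(profiles_b, dtype=float)
    if a.shape != b.shape or a.shape[0] < 1:
        raise ValueError("need matching, non-empty profile matrices")
    n_cond = a.shape[1]
    rows = []
    for i, j in combinations(range(n_cond), 2):
        fc_a = np.log2((a[:, i] + pseudocount) / (a[:, j] + pseudocount))
        fc_b = np.log2((b[:, i] + pseudocount) / (b[:, j] + pseudocount))
        for p in range(a.shape[0]):
            rows.append((p, i, j, fc_a[p], fc_b[p]))
    df = pd.DataFrame(rows, columns=["pair_index", "cond_i", "cond_j",
                                     "log2fc_a", "log2fc_b"])
    x, y = df["log2fc_a"].to_numpy(), df["log2fc_b"].to_numpy()
    if len(df) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan"), df
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r), df
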
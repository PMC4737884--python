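"""Stereotypy of brain-wide activity profiles: correlations and bootstrap.

Each animal contributes one activity vector over a shared region list
(c-FosGFP cell counts per region, or regional PET intensity).  Within-group
similarity is the mean pairwise Pearson correlation over animals of a
group.  The helpless-vs-resilient difference in that mean
(Correlation_LH - Correlation_R) is tested against a pooled bootstrap null:
each iteration resamples n1 animals with replacement from the combined pool
into a pseudo-LH group and n2 into a pseudo-R group, and records the
difference of the two resampled means.  The two-sided P locates the
observed difference in this null distribution.

Resampled groups are multisets: with the default convention a duplicated
animal contributes r = 1 pairs (the literal reading of resampling with
replacement); ``include_duplicate_pairs=False`` drops same-animal pairs
instead, redrawing iterations whose resample leaves no valid pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BootstrapConfig",
    "StereotypyTest",
    "StereotypyResults",
    "correlation_matrix",
    "mean_within_correlation",
    "bootstrap_null",
    "bootstrap_group_diff",
]


def correlation_matrix(vectors: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation between animals (rows = animals).

    Zero-variance animals are excluded with a warning (their r is
    undefined).  The diagonal is 1; the matrix is symmetric.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 animals")
    X = vectors.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("activity vectors must be finite")
    keep = X.std(axis=1) > 0
    if not keep.all():
        dropped = list(vectors.index[~keep])
        warnings.warn(f"excluding zero-variance animals {dropped}")
        vectors = vectors.loc[keep]
        X = X[keep]
    if len(X) < 2:
        raise ValueError("fewer than 2 animals with non-zero variance")
    C = np.corrcoef(X)
    return pd.DataFrame(C, index=vectors.index, columns=vectors.index)


def mean_within_correlation(vectors: pd.DataFrame) -> float:
    """Mean Pearson r over the off-diagonal upper triangle (the stereotypy statistic)."""
    C = correlation_matrix(vectors).to_numpy()
    iu = np.triu_indices(len(C), k=1)
    return float(C[iu].mean())


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: resample sizes, iteration count, seed, conventions.

    n1/n2 default to the 11 + 11 mouse design; the rat PET comparison uses
    8 + 8.  ``two_sided="doubled"`` doubles the smaller tail (ties counted
    as extreme); ``"abs"`` instead counts |null| >= |observed|.
    """

    n1: int = 11
    n2: int = 11
    n_iter: int = 100_000
    seed: int | None = None
    include_duplicate_pairs: bool = True
    two_sided: str = "doubled"
    max_redraw_rounds: int = 100

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("resample sizes must be at least 2")
        if self.n_iter < 1:
            raise ValueError("n_iter must be positive")
        if self.two_sided not in ("doubled", "abs"):
            raise ValueError("two_sided must be 'doubled' or 'abs'")


def _resample_means(
    C: np.ndarray,
    idx: np.ndarray,
    include_duplicate_pairs: bool,
) -> np.ndarray:
    """Mean pairwise r for each resampled multiset of animal indices.

    idx: (n_iter, k) pooled-animal indices.  Pairs are unordered pairs of
    list positions; duplicated positions hit the diagonal (r = 1) and are
    kept or dropped per the convention.  Iterations with no valid pair
    return NaN.
    """
    k = idx.shape[1]
    a, b = np.triu_indices(k, k=1)
    vals = C[idx[:, a], idx[:, b]]  # (n_iter, n_pairs)
    if include_duplicate_pairs:
        return vals.mean(axis=1)
    valid = idx[:, a] != idx[:, b]
    n_valid = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(valid, vals, 0.0).sum(axis=1) / n_valid
    means[n_valid == 0] = np.nan
    return means


def bootstrap_null(
    pool: pd.DataFrame,
    n1: int,
    n2: int,
    n_iter: int,
    seed: int | None = None,
    include_duplicate_pairs: bool = True,
    max_redraw_rounds: int = 100,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null sample of Correlation_LHnull - Correlation_Rnull from a pooled set.

    Each iteration draws n1 then n2 animals with replacement from the pool
    and takes the difference of the two resampled groups' mean pairwise
    correlations.  Iterations whose resample admits no valid pair (possible
    only when same-animal pairs are excluded) are redrawn, up to
    ``max_redraw_rounds`` passes.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    C = np.corrcoef(pool.to_numpy(dtype=float))
    m = len(pool)
    null = np.empty(n_iter)
    need = np.arange(n_iter)
    for _ in range(max_redraw_rounds):
        i1 = rng.integers(0, m, (len(need), n1))
        i2 = rng.integers(0, m, (len(need), n2))
        d = _resample_means(C, i1, include_duplicate_pairs) - _resample_means(
            C, i2, include_duplicate_pairs
        )
        null[need] = d
        need = need[np.isnan(d)]
        if need.size == 0:
            return null
    raise RuntimeError("too many degenerate resamples; relax the pair convention")


class StereotypyTest:
    """Bootstrap comparison of within-group activity-profile similarity.

    Built from the two groups' activity vectors (DataFrames indexed by
    animal, columns = shared region list, identical ordering).
    """

    def __init__(self, lh_vectors: pd.DataFrame, r_vectors: pd.DataFrame) -> None:
        if list(lh_vectors.columns) != list(r_vectors.columns):
            raise ValueError("both groups must share one region list (same order)")
        if len(lh_vectors) < 2 or len(r_vectors) < 2:
            raise ValueError("each group needs at least 2 animals")
        self.lh = lh_vectors
        self.r = r_vectors
        self.pool = pd.concat([lh_vectors, r_vectors], axis=0)
        X = self.pool.to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("activity vectors must be finite")
        if np.any(X.std(axis=1) == 0):
            raise ValueError("zero-variance activity vector; correlations are undefined")

    def fit(self, config: BootstrapConfig | None = None, **kwargs) -> "StereotypyResults":
        cfg = config or BootstrapConfig(**kwargs)
        rng = np.random.default_rng(cfg.seed)
        C = np.corrcoef(self.pool.to_numpy(dtype=float))
        m = len(self.pool)
        n_lh = len(self.lh)
        lh_idx = np.arange(n_lh)
        r_idx = np.arange(n_lh, m)
        obs = float(
            _resample_means(C, lh_idx[None, :], True)[0]
            - _resample_means(C, r_idx[None, :], True)[0]
        )

        null = bootstrap_null(
            self.pool,
            cfg.n1,
            cfg.n2,
            cfg.n_iter,
            include_duplicate_pairs=cfg.include_duplicate_pairs,
            max_redraw_rounds=cfg.max_redraw_rounds,
            rng=rng,
        )

        if cfg.two_sided == "doubled":
            ge = int(np.sum(null >= obs))
            le = int(np.sum(null <= obs))
            p = min(1.0, 2.0 * min(ge, le) / cfg.n_iter)
        else:
            p = float(np.mean(np.abs(null) >= abs(obs)))
        p = max(p, 1.0 / cfg.n_iter)  # observed position cannot certify p = 0
        return StereotypyResults(
            model=self,
            config=cfg,
            observed_diff=obs,
            mean_corr_lh=float(_resample_means(C, lh_idx[None, :], True)[0]),
            mean_corr_r=float(_resample_means(C, r_idx[None, :], True)[0]),
            null_diffs=null,
            p_two_sided=float(p),
        )


@dataclass
class StereotypyResults:
    """Observed stereotypy difference, bootstrap null sample, and two-sided P."""

    model: StereotypyTest
    config: BootstrapConfig
    observed_diff: float
    mean_corr_lh: float
    mean_corr_r: float
    null_diffs: np.ndarray
    p_two_sided: float

    def summary(self) -> str:
        lines = [
            "Bootstrap test of within-group activity-profile similarity",
            f"  groups: {len(self.model.lh)} helpless, {len(self.model.r)} resilient; "
            f"{self.model.pool.shape[1]} regions",
            f"  mean within-group r: helpless {self.mean_corr_lh:.4f}, "
            f"resilient {self.mean_corr_r:.4f}",
            f"  observed difference (LH - R): {self.observed_diff:+.4f}",
            f"  null: {self.config.n_iter} pooled resamples "
            f"(n1 = {self.config.n1}, n2 = {self.config.n2})",
            f"  two-sided P = {self.p_two_sided:.4g}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, bins: int = 60):
        """Null histogram with the observed difference marked in red."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.null_diffs, bins=bins, color="steelblue", alpha=0.8)
        ax.axvline(self.observed_diff, color="red", lw=2)
        ax.set_xlabel("null difference of mean within-group r")
        ax.set_ylabel("iterations")
        ax.set_title(f"two-sided P = {self.p_two_sided:.3g}")
        return ax


def bootstrap_group_diff(
    lh_vectors: pd.DataFrame, r_vectors: pd.DataFrame, config: BootstrapConfig | None = None, **kwargs
) -> StereotypyResults:
    """Convenience wrapper around :class:`StereotypyTest`."""
    return StereotypyTest(lh_vectors, r_vectors).fit(config=config, **kwargs)
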
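"""Shuttle-box behavioral scoring and helpless/resilient phenotyping.

The learned-helplessness (LH) testing session presents a 5 s cue light
followed by a 10 s escapable foot shock.  A trial is scored as

* **avoidance** — the animal shuttles during the cue (shuttle time < 5 s;
  no shock is delivered, so no escape latency exists),
* **escape** — the animal shuttles during the shock (5 s <= shuttle time
  < 15 s; escape latency = shuttle time - 5 s, measured from shock onset),
* **failure** — no shuttle before the shock ends (escape latency censored
  at the 10 s shock duration).

Animals are phenotyped on two session indices, the mean escape latency and
the number of failures, either by k-means (k = 2) clustering of a cohort or
by linear classification functions of the Fisher-discriminant form

    score_k = x' S^-1 m_k - 0.5 m_k' S^-1 m_k + log pi_k

with pooled within-class covariance S; an animal is resilient when the
resilient-class score exceeds the helpless-class score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "TrialRecord",
    "SessionSummary",
    "DiscriminantModel",
    "ClassificationResult",
    "PAPER_DISCRIMINANT",
    "score_trial",
    "summarize_session",
    "summarize_cohort",
    "kmeans_phenotypes",
    "fit_discriminant",
    "discriminant_classify",
    "classify_rat",
    "compare_groups",
    "select_extreme_pairs",
]

CUE_DURATION_S = 5.0
SHOCK_DURATION_S = 10.0
TRIAL_WINDOW_S = CUE_DURATION_S + SHOCK_DURATION_S  # shuttle after 15 s = failure
N_SCORED_TRIALS = 30
N_UNSCORED_LEAD_TRIALS = 5

RESILIENT = "resilient"
HELPLESS = "helpless"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class TrialRecord:
    """One scored shuttle-box trial."""

    trial_index: int
    shuttle_time: float | None  # seconds from cue onset; None = never shuttled
    outcome: str  # avoidance | escape | failure
    escape_latency: float | None  # seconds from shock onset; None for avoidance


@dataclass(frozen=True)
class SessionSummary:
    """Per-animal indices of a testing session used for classification."""

    animal_id: str
    mean_escape_latency: float
    n_failures: int


@dataclass(frozen=True)
class DiscriminantModel:
    """Linear classification functions for the two phenotypes.

    Each coefficient triple is (intercept, latency weight, failures weight);
    an animal is resilient iff its resilient score exceeds its helpless score.
    """

    coef_R: tuple[float, float, float]
    coef_LH: tuple[float, float, float]

    def scores(self, mean_escape_latency: float, n_failures: float) -> tuple[float, float]:
        x = (1.0, float(mean_escape_latency), float(n_failures))
        r = sum(c * v for c, v in zip(self.coef_R, x))
        lh = sum(c * v for c, v in zip(self.coef_LH, x))
        return r, lh


@dataclass(frozen=True)
class ClassificationResult:
    animal_id: str
    R_score: float
    LH_score: float
    label: str


#: Classification functions reported for the 144-mouse cohort; usable on new
#: cases without refitting.
PAPER_DISCRIMINANT = DiscriminantModel(
    coef_R=(-4.63, 5.67, -1.65),
    coef_LH=(-23.24, 3.67, 0.53),
)


def score_trial(shuttle_time: float | None, trial_index: int = 0) -> TrialRecord:
    """Score a single trial from the shuttle time (seconds from cue onset).

    ``None`` or NaN means the animal never shuttled.  Shuttling at or after
    the 15 s trial window also counts as failure (the shock has ended).
    """
    if shuttle_time is not None and not math.isnan(shuttle_time):
        t = float(shuttle_time)
        if t < 0:
            raise ValueError(f"shuttle_time must be non-negative, got {t}")
        if t < CUE_DURATION_S:
            return TrialRecord(trial_index, t, "avoidance", None)
        if t < TRIAL_WINDOW_S:
            return TrialRecord(trial_index, t, "escape", t - CUE_DURATION_S)
    else:
        t = None
    return TrialRecord(trial_index, t, "failure", SHOCK_DURATION_S)


def _scored_trials(trials: Sequence[TrialRecord]) -> Sequence[TrialRecord]:
    if len(trials) == N_SCORED_TRIALS:
        return trials
    if len(trials) >= N_UNSCORED_LEAD_TRIALS + N_SCORED_TRIALS:
        return trials[N_UNSCORED_LEAD_TRIALS : N_UNSCORED_LEAD_TRIALS + N_SCORED_TRIALS]
    raise ValueError(
        f"need exactly {N_SCORED_TRIALS} pre-scored trials or >= "
        f"{N_UNSCORED_LEAD_TRIALS + N_SCORED_TRIALS} raw trials, got {len(trials)}"
    )


def summarize_session(trials: Sequence[TrialRecord], animal_id: str = "") -> SessionSummary:
    """Summarize a session into (mean escape latency, failure count).

    The first five trials of a full 35-trial session are discarded
    (association learning).  The latency mean runs over escape and failure
    trials (failures contribute the censored 10 s); avoidance trials carry
    no escape latency and are excluded.  An all-avoidance session gets
    latency 0.
    """
    scored = _scored_trials(trials)
    n_failures = sum(1 for t in scored if t.outcome == "failure")
    latencies = [t.escape_latency for t in scored if t.escape_latency is not None]
    mean_lat = float(np.mean(latencies)) if latencies else 0.0
    return SessionSummary(animal_id=animal_id, mean_escape_latency=mean_lat, n_failures=n_failures)


def summarize_cohort(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Summarize a per-trial table (animal_id, trial_index, shuttle_time).

    NaN shuttle_time marks a failure.  Returns one row per animal with
    mean_escape_latency and n_failures.
    """
    rows = []
    for animal_id, grp in trial_table.groupby("animal_id", sort=True):
        grp = grp.sort_values("trial_index")
        trials = [
            score_trial(None if pd.isna(t) else float(t), int(i))
            for i, t in zip(grp["trial_index"], grp["shuttle_time"])
        ]
        s = summarize_session(trials, animal_id=str(animal_id))
        rows.append(
            {
                "animal_id": s.animal_id,
                "mean_escape_latency": s.mean_escape_latency,
                "n_failures": s.n_failures,
            }
        )
    return pd.DataFrame(rows)


def kmeans_phenotypes(
    summaries: pd.DataFrame, k: int = 2, seed: int | None = 0, n_init: int = 50
) -> tuple[pd.Series, pd.DataFrame]:
    """Cluster animals into helpless/resilient on (latency, failures).

    k is fixed at 2 (one helpless and one resilient cluster); the cluster
    with the larger mean failure count is named helpless.  Features are
    used in raw units (seconds, counts).  Multi-restart k-means++ with a
    fixed seed makes the assignment deterministic.

    Returns (labels indexed like ``summaries``, centers frame indexed by
    phenotype name).
    """
    if k != 2:
        raise ValueError("k is fixed at 2 (helpless vs resilient)")
    X = summaries[["mean_escape_latency", "n_failures"]].to_numpy(dtype=float)
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError("need at least 2 distinct (latency, failures) points to cluster")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    # name clusters by failure count, not by arbitrary init order
    fail_means = [X[raw == c, 1].mean() for c in range(k)]
    helpless_cluster = int(np.argmax(fail_means))
    names = np.where(raw == helpless_cluster, HELPLESS, RESILIENT)
    labels = pd.Series(names, index=summaries.index, name="kmeans_label")
    centers = pd.DataFrame(
        km.cluster_centers_,
        columns=["mean_escape_latency", "n_failures"],
        index=[HELPLESS if c == helpless_cluster else RESILIENT for c in range(k)],
    )
    return labels, centers


def fit_discriminant(
    summaries: pd.DataFrame,
    labels: Iterable[str],
    priors: tuple[float, float] | None = None,
) -> DiscriminantModel:
    """Fit Fisher linear classification functions to labelled summaries.

    Uses the classical closed form with pooled within-class covariance
    (unbiased, N - 2 denominator) and class priors (empirical unless given
    as (resilient, helpless)).  The induced boundary is the perpendicular
    bisector of the class means in the Mahalanobis metric, shifted by
    log(pi_R / pi_LH).
    """
    X = summaries[["mean_escape_latency", "n_failures"]].to_numpy(dtype=float)
    y = np.asarray(list(labels))
    classes = [RESILIENT, HELPLESS]
    if not all((y == c).any() for c in classes):
        raise ValueError("both phenotypes must be present to fit a discriminant")
    mus, ns, sw = [], [], np.zeros((2, 2))
    for c in classes:
        Xc = X[y == c]
        mus.append(Xc.mean(axis=0))
        ns.append(len(Xc))
        sw += (Xc - Xc.mean(axis=0)).T @ (Xc - Xc.mean(axis=0))
    pooled = sw / (sum(ns) - 2)
    if np.linalg.matrix_rank(pooled) < 2 or np.linalg.cond(pooled) > 1e12:
        raise np.linalg.LinAlgError(
            "pooled within-class covariance is singular; classes are degenerate "
            "in (latency, failures)"
        )
    prec = np.linalg.inv(pooled)
    if priors is None:
        priors = (ns[0] / sum(ns), ns[1] / sum(ns))
    coefs = []
    for mu, pi in zip(mus, priors):
        w = prec @ mu
        b = -0.5 * mu @ prec @ mu + math.log(pi)
        coefs.append((float(b), float(w[0]), float(w[1])))
    return DiscriminantModel(coef_R=coefs[0], coef_LH=coefs[1])


def discriminant_classify(
    summary: SessionSummary, model: DiscriminantModel = PAPER_DISCRIMINANT
) -> ClassificationResult:
    """Classify one animal with linear classification functions.

    Resilient iff R score > LH score; a higher score reflects a smaller
    squared Mahalanobis distance to that phenotype's centroid.
    """
    r, lh = model.scores(summary.mean_escape_latency, summary.n_failures)
    label = RESILIENT if r > lh else HELPLESS
    return ClassificationResult(summary.animal_id, r, lh, label)


def classify_rat(lever_presses_within_20s: int, n_trials: int = 15) -> str:
    """Classify a rat from lever presses within 20 s of shock onset.

    >= 10 presses over the 15 test trials = resilient; <= 5 = helpless;
    the intermediate band (6-9) is excluded from analysis.
    """
    n = int(lever_presses_within_20s)
    if n < 0:
        raise ValueError("lever press count cannot be negative")
    if n > n_trials:
        raise ValueError(f"at most one scorable press per trial ({n_trials} trials), got {n}")
    if n >= 10:
        return RESILIENT
    if n <= 5:
        return HELPLESS
    return EXCLUDED


def compare_groups(summaries: pd.DataFrame, labels: Iterable[str]) -> pd.DataFrame:
    """Mann-Whitney comparison of the two phenotypes on both session indices.

    Returns a frame indexed by index name with the U statistic of the
    helpless sample, the rank-sum W of the helpless sample, and the
    two-tailed P (midranks for ties; exact when tie-free and small).
    """
    y = np.asarray(list(labels))
    rows = {}
    for col in ("n_failures", "mean_escape_latency"):
        a = summaries.loc[y == HELPLESS, col].to_numpy(dtype=float)
        b = summaries.loc[y == RESILIENT, col].to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            raise ValueError("both groups must be non-empty")
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows[col] = {
            "U": float(res.statistic),
            "W": float(res.statistic + len(a) * (len(a) + 1) / 2),
            "p_value": float(res.pvalue),
            "n_helpless": len(a),
            "n_resilient": len(b),
        }
    return pd.DataFrame(rows).T


def select_extreme_pairs(
    summaries: pd.DataFrame, labels: Iterable[str], batches: Iterable
) -> pd.DataFrame:
    """Pick one extreme helpless + one extreme resilient animal per batch.

    Within each batch (animals run through the procedure in parallel), the
    helpless member maximizes (n_failures, mean_escape_latency) in
    lexicographic order and the resilient member minimizes them.  Batches
    missing either phenotype are skipped with a warning.  Returns a pair
    design frame (pair_id, helpless_id, resilient_id).
    """
    df = summaries.copy()
    df["label"] = np.asarray(list(labels))
    df["batch"] = np.asarray(list(batches))
    pairs = []
    for pair_id, (batch, grp) in enumerate(iter(df.groupby("batch", sort=True)), start=1):
        h = grp[grp["label"] == HELPLESS]
        r = grp[grp["label"] == RESILIENT]
        if h.empty or r.empty:
            warnings.warn(f"batch {batch!r} lacks a {'helpless' if h.empty else 'resilient'} animal; skipped")
            continue
        h_best = h.sort_values(
            ["n_failures", "mean_escape_latency"], ascending=[False, False]
        ).iloc[0]
        r_best = r.sort_values(
            ["n_failures", "mean_escape_latency"], ascending=[True, True]
        ).iloc[0]
        pairs.append(
            {
                "pair_id": f"P{pair_id}",
                "batch": batch,
                "helpless_id": h_best["animal_id"],
                "resilient_id": r_best["animal_id"],
            }
        )
    return pd.DataFrame(pairs, columns=["pair_id", "batch", "helpless_id", "resilient_id"])
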
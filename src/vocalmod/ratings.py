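"""Per-speaker performance measures derived from naive listener ratings.

The measures implemented here are:

* ``delta_trait`` -- mean listener-rating change of a trait-modulated
  recording over the same speaker's neutral recording, on that trait's
  own scale (in Likert points).
* ``build_rsm`` -- a 3x3 rating similarity matrix (RSM) of pairwise
  Pearson correlations between the likeable / hostile / intelligent
  rating-scale vectors for one speaker.
* ``modulation_index`` -- Euclidean distance of a speaker's RSM to the
  theoretical maximal-discrimination matrix, computed over the three
  unique off-diagonal cells.  Lower values mean higher specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: All recording conditions present in the design.
CONDITIONS = ("neutral", "large", "hostile", "likeable", "intelligent")

#: Axis order of the RSM: (likeable, hostile, intelligent).
SOCIAL_TRAITS = ("likeable", "hostile", "intelligent")

#: Output column names for the delta-trait indices.
DELTA_COLUMNS = {
    "hostile": "delta_hostility",
    "likeable": "delta_likeability",
    "intelligent": "delta_intelligence",
}

RATING_COLUMNS = ("listener_id", "speaker_id", "condition", "scale", "rating")

_EDGE_TOL = 1e-9


class InsufficientDataError(ValueError):
    """No complete listener pair / block available for a computation."""


class DegenerateCellError(ValueError):
    """A scale vector entering an RSM cell has zero variance."""


class InvalidMatrixError(ValueError):
    """A matrix is not a valid (symmetric, unit-diagonal) correlation matrix."""


def theoretical_rsm() -> np.ndarray:
    """Return the fixed maximal-discrimination correlation matrix.

    Axis order follows :data:`SOCIAL_TRAITS`: likeable/hostile are fully
    anti-correlated (-1) and intelligent is uncorrelated with both (0).
    """
    return np.array(
        [
            [1.0, -1.0, 0.0],
            [-1.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
        ]
    )


def _validate_corr_matrix(m: np.ndarray, name: str = "matrix") -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise InvalidMatrixError(f"{name} must be 3x3, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise InvalidMatrixError(f"{name} contains non-finite values")
    if np.max(np.abs(m - m.T)) > _EDGE_TOL:
        raise InvalidMatrixError(f"{name} is asymmetric beyond tolerance {_EDGE_TOL}")
    if np.max(np.abs(np.diag(m) - 1.0)) > _EDGE_TOL:
        raise InvalidMatrixError(f"{name} diagonal is not 1")
    if np.max(np.abs(m)) > 1.0 + _EDGE_TOL:
        raise InvalidMatrixError(f"{name} has cells outside [-1, 1]")
    return m


def modulation_index(rsm: np.ndarray, theoretical: np.ndarray | None = None) -> float:
    """Euclidean distance between two 3x3 correlation matrices.

    Computed over the three unique off-diagonal cells only, i.e.::

        ED = sqrt(sum_{i<j} (r_ij - t_ij)^2)

    which gives 0 for a perfect match and sqrt(6) ~= 2.45 for the
    maximally distant matrix (all off-diagonals +1 against the
    theoretical -1/0/0 pattern).
    """
    if theoretical is None:
        theoretical = theoretical_rsm()
    rsm = _validate_corr_matrix(rsm, "rsm")
    theoretical = _validate_corr_matrix(theoretical, "theoretical")
    iu = np.triu_indices(3, k=1)
    diff = rsm[iu] - theoretical[iu]
    return float(np.sqrt(np.sum(diff**2)))


def _speaker_frame(records: pd.DataFrame, speaker_id) -> pd.DataFrame:
    sub = records[records["speaker_id"] == speaker_id]
    if sub.empty:
        raise InsufficientDataError(f"no ratings for speaker {speaker_id!r}")
    return sub


def delta_trait(records: pd.DataFrame, speaker_id, trait: str) -> float:
    """Mean paired change in trait ratings: modulated minus neutral.

    For each listener who rated both the ``trait``-modulated recording and
    the neutral recording on the trait's own scale, take the difference;
    return the mean over listeners.  Listeners missing either member of
    the pair are dropped (count logged).

    Raises
    ------
    InsufficientDataError
        If no listener contributes a complete pair.
    """
    if trait not in DELTA_COLUMNS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {sorted(DELTA_COLUMNS)}")
    sub = _speaker_frame(records, speaker_id)
    sub = sub[sub["scale"] == trait]
    mod = sub[sub["condition"] == trait].set_index("listener_id")["rating"]
    neu = sub[sub["condition"] == "neutral"].set_index("listener_id")["rating"]
    common = mod.index.intersection(neu.index)
    dropped = len(mod.index.union(neu.index)) - len(common)
    if dropped:
        logger.info(
            "delta_trait(%r, %s): excluded %d listener(s) missing a pair member",
            speaker_id,
            trait,
            dropped,
        )
    if len(common) == 0:
        raise InsufficientDataError(
            f"no complete (modulated, neutral) listener pair for speaker "
            f"{speaker_id!r}, trait {trait!r}"
        )
    diffs = mod.loc[common].to_numpy(dtype=float) - neu.loc[common].to_numpy(dtype=float)
    return float(np.mean(diffs))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt(np.sum(x**2) * np.sum(y**2))
    return float(np.sum(x * y) / denom)


def build_rsm(records: pd.DataFrame, speaker_id, mode: str = "scalewise") -> np.ndarray:
    """Build the 3x3 rating similarity matrix for one speaker.

    Only the three social-trait recordings (likeable, hostile,
    intelligent) enter; neutral and large conditions are excluded.
    Listeners contribute only if they rated all three recordings on all
    three scales (complete 3x3 block).

    mode="scalewise" (default): cell (i, j) is the Pearson correlation
    between the scale-i and scale-j rating vectors, each stacking the
    ratings over (listener x recording) -- length 3L for L listeners.

    mode="profile": cell (i, j) correlates the *recording*-i and
    recording-j rating profiles (all three scales stacked over
    listeners).  Exposed as the alternative reading of the cell
    semantics.
    """
    if mode not in ("scalewise", "profile"):
        raise ValueError(f"unknown rsm mode {mode!r}")
    sub = _speaker_frame(records, speaker_id)
    sub = sub[sub["condition"].isin(SOCIAL_TRAITS) & sub["scale"].isin(SOCIAL_TRAITS)]
    # listeners with a complete 3 conditions x 3 scales block
    counts = sub.groupby("listener_id").size()
    complete = counts[counts == 9].index
    dropped = len(counts) - len(complete)
    if dropped:
        logger.info(
            "build_rsm(%r): excluded %d listener(s) with incomplete blocks",
            speaker_id,
            dropped,
        )
    if len(complete) == 0:
        raise InsufficientDataError(
            f"no listener with a complete social-trait block for speaker {speaker_id!r}"
        )
    sub = sub[sub["listener_id"].isin(complete)]
    wide = sub.pivot_table(
        index=["listener_id", "condition"],
        columns="scale",
        values="rating",
        aggfunc="first",
        sort=True,
    )

    if mode == "scalewise":
        vectors = [wide[scale].to_numpy(dtype=float) for scale in SOCIAL_TRAITS]
        labels = list(SOCIAL_TRAITS)
    else:  # profile: one vector per recording across (listener x scale)
        prof = sub.pivot_table(
            index=["listener_id", "scale"],
            columns="condition",
            values="rating",
            aggfunc="first",
            sort=True,
        )
        vectors = [prof[cond].to_numpy(dtype=float) for cond in SOCIAL_TRAITS]
        labels = list(SOCIAL_TRAITS)

    for lab, v in zip(labels, vectors):
        if np.allclose(v, v[0]):
            raise DegenerateCellError(
                f"zero-variance vector for {lab!r} (speaker {speaker_id!r}); "
                "RSM cell undefined"
            )
    rsm = np.eye(3)
    for i in range(3):
        for j in range(i + 1, 3):
            r = _pearson(vectors[i], vectors[j])
            rsm[i, j] = rsm[j, i] = r
    return rsm


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def delta_ttest(deltas, tail: str = "two-sided") -> TTestResult:
    """One-sample t test of delta-trait values against zero.

    ``tail`` is "two-sided" or "greater" (one-sided, H1: mean > 0).
    Zero-variance input yields an infinite-t flagged result rather than
    an exception.
    """
    if tail not in ("two-sided", "greater"):
        raise ValueError(f"tail must be 'two-sided' or 'greater', got {tail!r}")
    x = np.asarray(deltas, dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientDataError("need at least 2 observations for a t test")
    df = n - 1
    m = x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        t = np.inf * np.sign(m) if m != 0 else 0.0
        p = 0.0 if m != 0 else 1.0
        if tail == "greater" and m < 0:
            p = 1.0
        return TTestResult(float(t), df, float(p), degenerate=True)
    t = m / (sd / np.sqrt(n))
    if tail == "two-sided":
        p = 2.0 * stats.t.sf(abs(t), df)
    else:
        p = stats.t.sf(t, df)
    return TTestResult(float(t), df, float(p))


def speaker_performance(records: pd.DataFrame, rsm_mode: str = "scalewise") -> pd.DataFrame:
    """Per-speaker performance table.

    Returns a DataFrame with one row per speaker and columns
    ``speaker_id``, ``delta_hostility``, ``delta_likeability``,
    ``delta_intelligence``, ``ed`` and ``neutral_likeability`` (mean
    likeable-scale rating of the neutral recording, used by the control
    analysis downstream).
    """
    theo = theoretical_rsm()
    rows = []
    for speaker_id in sorted(records["speaker_id"].unique()):
        row: dict = {"speaker_id": speaker_id}
        for trait, col in DELTA_COLUMNS.items():
            row[col] = delta_trait(records, speaker_id, trait)
        rsm = build_rsm(records, speaker_id, mode=rsm_mode)
        row["ed"] = modulation_index(rsm, theo)
        neu = records[
            (records["speaker_id"] == speaker_id)
            & (records["condition"] == "neutral")
            & (records["scale"] == "likeable")
        ]["rating"]
        row["neutral_likeability"] = float(neu.mean()) if len(neu) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def rsm_long(records: pd.DataFrame, rsm_mode: str = "scalewise") -> pd.DataFrame:
    """Long-format per-speaker RSM table (speaker_id, pair, r)."""
    rows = []
    for speaker_id in sorted(records["speaker_id"].unique()):
        rsm = build_rsm(records, speaker_id, mode=rsm_mode)
        for i in range(3):
            for j in range(i + 1, 3):
                rows.append(
                    {
                        "speaker_id": speaker_id,
                        "pair": f"{SOCIAL_TRAITS[i]}-{SOCIAL_TRAITS[j]}",
                        "r": rsm[i, j],
                    }
                )
    return pd.DataFrame(rows)
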
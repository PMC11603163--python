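"""Per-position, per-group conservation grading on reference coordinates.

Each alignment column, restricted to the rows of one paralog group, gets a
raw conservation score

    score = JSD'(p_column, background) * (non-gap fraction)

where ``p_column`` is the amino-acid frequency distribution of the column
(gaps and X excluded), ``background`` is a fixed amino-acid background
(Robinson-Robinson database frequencies by default, uniform on request),
and JSD' is the Jensen-Shannon divergence in bits, which for two
distributions lies in [0, 1].  A column whose composition diverges strongly
from the background -- in practice a column dominated by one residue -- is
conserved; a column that looks like a random draw from the background is
not.  The non-gap fraction downweights gappy columns, so a half-gapped
invariant column scores exactly half its gap-free counterpart.

Raw scores are then rank-binned *within each group* into nine
equal-frequency grades (9 = most conserved ninth, matching the ConSurf
convention), which makes grades comparable across groups of different sizes
-- the property the exclusive-conservation subtraction requires.  Columns
with fewer informative residues than ``min_coverage`` are UNDEFINED;
positions inside the CTD mask are MASKED.  Both are excluded from binning
and propagate downstream as an exclusive-conservation score of zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.distance import jensenshannon
from scipy.stats import rankdata

from .seqio_filter import AA20, AlignmentSet, ColumnMap, MaskSpec

#: Grade sentinels (grades proper are 1..9).
GRADE_UNDEFINED = 0
GRADE_MASKED = -1

#: Robinson & Robinson (1991) amino-acid background frequencies, indexed as AA20.
ROBINSON_ROBINSON = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}


def background_frequencies(name: str = "robinson") -> np.ndarray:
    """Background distribution over AA20 ('robinson' or 'uniform')."""
    if name == "robinson":
        bg = np.array([ROBINSON_ROBINSON[aa] for aa in AA20], dtype=float)
    elif name == "uniform":
        bg = np.full(20, 1.0 / 20.0)
    else:
        raise ValueError(f"unknown background {name!r}")
    return bg / bg.sum()


@dataclass
class ConservationProfile:
    """Conservation grades for one group over reference positions 1..ref_length.

    ``grades[i-1]`` is the grade at reference position i: 1..9, or the
    sentinels GRADE_MASKED / GRADE_UNDEFINED.  ``raw_scores`` holds the
    pre-binning scores (NaN where masked or undefined); ``coverage`` the
    per-position count of informative (non-gap, non-X) residues.
    """

    group: str
    grades: np.ndarray
    raw_scores: np.ndarray
    coverage: np.ndarray

    @property
    def ref_length(self) -> int:
        return len(self.grades)

    def is_defined(self) -> np.ndarray:
        return self.grades >= 1


def _count_matrix(columns: Sequence[str] | np.ndarray) -> np.ndarray:
    """20 x n_columns residue count matrix from a list of column strings."""
    n = len(columns)
    counts = np.zeros((20, n), dtype=float)
    for j, col in enumerate(columns):
        for ch in col:
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[idx, j] += 1
    return counts


def _scores_from_counts(
    counts: np.ndarray, n_rows: int, background: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Raw scores and coverage for a count matrix; NaN where no residues."""
    coverage = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / coverage
    jsd = np.empty(counts.shape[1])
    informative = coverage > 0
    if informative.any():
        js_dist = jensenshannon(
            p[:, informative], background[:, None], base=2, axis=0
        )
        # jensenshannon returns the distance (sqrt of the divergence).
        jsd_vals = np.square(np.nan_to_num(js_dist, nan=0.0))
        jsd[informative] = np.clip(jsd_vals, 0.0, 1.0)
    jsd[~informative] = np.nan
    scores = jsd * (coverage / n_rows)
    return scores, coverage.astype(int)


def column_score(
    column: Iterable[str], background: np.ndarray | str = "robinson"
) -> Optional[float]:
    """Raw conservation score of one alignment column, or None when the
    column holds no informative residue (entirely gaps/X)."""
    if isinstance(background, str):
        background = background_frequencies(background)
    col = "".join(column)
    if not col:
        raise ValueError("column must be non-empty")
    counts = _count_matrix([col])
    scores, coverage = _scores_from_counts(counts, len(col), background)
    if coverage[0] == 0:
        return None
    return float(scores[0])


def bin_grades(raw_scores: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Rank-bin raw scores into 9 equal-frequency grades (9 = top ninth).

    Ties receive the grade of their mean rank, so equal scores always share
    a grade and grades are a monotone function of the raw score.
    """
    grades = np.full(len(raw_scores), GRADE_UNDEFINED, dtype=int)
    n = int(valid.sum())
    if n == 0:
        return grades
    ranks = rankdata(raw_scores[valid], method="average")
    g = np.ceil(ranks * 9.0 / n).astype(int)
    grades[valid] = np.clip(g, 1, 9)
    return grades


def group_profile(
    aln: AlignmentSet,
    cmap: ColumnMap,
    group: str,
    mask: Optional[MaskSpec] = None,
    min_coverage: int = 4,
    background: np.ndarray | str = "robinson",
) -> ConservationProfile:
    """Conservation profile of one group over the reference positions.

    For each reference position the corresponding alignment column is
    restricted to the group's rows and scored; scores are then rank-binned
    into grades within the group.  Positions with fewer than
    ``min_coverage`` informative residues are UNDEFINED, masked positions
    MASKED.
    """
    if isinstance(background, str):
        background = background_frequencies(background)
    if min_coverage < 2:
        raise ValueError("min_coverage must be >= 2")
    rows = aln.group_rows(group)
    if not rows:
        raise ValueError(f"unknown or empty group {group!r}")
    if len(rows) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 rows")
    L = cmap.ref_length
    cols = [
        "".join(row[cmap.ref_to_col[i] - 1] for row in rows)
        for i in range(1, L + 1)
    ]
    counts = _count_matrix(cols)
    raw, coverage = _scores_from_counts(counts, len(rows), background)

    undefined = coverage < min_coverage
    masked = np.zeros(L, dtype=bool)
    if mask is not None:
        mask.validate(L)
        for a, b in mask.intervals:
            masked[a - 1 : b] = True
    valid = ~undefined & ~masked
    raw = np.where(valid, raw, np.nan)
    grades = bin_grades(raw, valid)
    grades[masked] = GRADE_MASKED
    return ConservationProfile(
        group=group, grades=grades, raw_scores=raw, coverage=coverage
    )


def profiles_for_groups(
    aln: AlignmentSet,
    cmap: ColumnMap,
    groups: Sequence[str],
    mask: Optional[MaskSpec] = None,
    min_coverage: int = 4,
    background: np.ndarray | str = "robinson",
) -> dict[str, ConservationProfile]:
    """Convenience: one profile per requested group."""
    return {
        g: group_profile(aln, cmap, g, mask, min_coverage, background)
        for g in groups
    }
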
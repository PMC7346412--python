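"""Alignment summary statistics and one-sample comparative tests.

Covers the descriptive and inferential comparisons of a focal genome against
a species panel: alignment length / gap fraction / parsimony-informative
sites, one-tailed one-sample t-tests (e.g. genome size, plastid read
fraction), and the plastid read fraction itself from mapped-read counts or a
SAM stream.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sps

GAP_CHARS = frozenset("-?")
UNAMBIGUOUS = frozenset("ACGT")


@dataclasses.dataclass
class AlignmentStats:
    length: int
    gap_fraction: float
    parsimony_informative: int


def alignment_stats(alignment: dict[str, str]) -> AlignmentStats:
    """Length, gap fraction and parsimony-informative column count.

    A column is parsimony-informative iff at least two distinct unambiguous
    states (A/C/G/T) each occur in at least two sequences; gaps ('-', '?')
    are missing data and IUPAC ambiguity codes are excluded from state counts.
    """
    rows = [s.upper() for s in alignment.values()]
    if not rows:
        raise ValueError("empty alignment")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    (n_cols,) = lengths
    mat = np.array([list(r) for r in rows])
    gap_fraction = float(np.isin(mat, list(GAP_CHARS)).mean()) if n_cols else 0.0
    informative = 0
    for j in range(n_cols):
        col = mat[:, j]
        states, counts = np.unique(col[np.isin(col, list(UNAMBIGUOUS))],
                                   return_counts=True)
        if (counts >= 2).sum() >= 2:
            informative += 1
    return AlignmentStats(length=n_cols, gap_fraction=gap_fraction,
                          parsimony_informative=informative)


def one_tailed_t(panel_values, focal_value: float, alternative: str) -> float:
    """One-sample, one-tailed t-test of the panel mean against a focal value.

    t = (mean − focal)/(sd/√n) with n−1 df.  ``alternative`` states the
    direction explicitly: ``panel_mean_greater`` tests whether the panel mean
    exceeds the focal value, ``panel_mean_less`` the reverse.
    """
    x = np.asarray(list(panel_values), dtype=float)
    if x.size < 3:
        raise ValueError("panel needs at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("panel has zero variance")
    t = (x.mean() - focal_value) / (sd / np.sqrt(x.size))
    if alternative == "panel_mean_greater":
        return float(sps.t.sf(t, df=x.size - 1))
    if alternative == "panel_mean_less":
        return float(sps.t.cdf(t, df=x.size - 1))
    raise ValueError(f"unknown alternative {alternative!r}")


def plastid_read_fraction(source) -> float:
    """Percent of reads mapping to the plastid, from counts or a SAM file.

    ``source`` is either ``{"mapped_to_plastid": int, "total_reads": int}``
    or a path to a SAM file, in which case primary records are counted
    (secondary and supplementary alignments excluded) and mapped means the
    unmapped flag is clear.
    """
    if isinstance(source, dict):
        mapped = int(source["mapped_to_plastid"])
        total = int(source["total_reads"])
    else:
        import pysam

        mapped = total = 0
        with pysam.AlignmentFile(str(source), "r", check_sq=False) as fh:
            for read in fh:
                if read.is_secondary or read.is_supplementary:
                    continue
                total += 1
                if not read.is_unmapped:
                    mapped += 1
    if total <= 0:
        raise ValueError("total read count must be positive")
    return 100.0 * mapped / total
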
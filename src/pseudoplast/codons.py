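"""Genetic-code tables and the 61 sense-codon state space.

Plastid protein-coding genes are translated with the bacterial/plastid code
(NCBI translation table 11), whose codon→amino-acid map is identical to the
standard code; only the permitted start codons differ.  Codon-model code
(GY94 likelihoods, codon simulation) works on the 61 sense codons in a fixed
deterministic order; the three stops (TAA, TAG, TGA) are excluded states.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

DEFAULT_TABLE_ID = 11

NUCS = "TCAG"  # position ordering used to enumerate codons (PAML convention)
PURINES = frozenset("AG")

_table = CodonTable.unambiguous_dna_by_id[DEFAULT_TABLE_ID]
STOP_CODONS = tuple(sorted(_table.stop_codons))
ALL_CODONS = tuple(a + b + c for a in NUCS for b in NUCS for c in NUCS)
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in _table.stop_codons)
N_STATES = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AA_OF_CODON = {c: _table.forward_table[c] for c in SENSE_CODONS}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a→b is a transition (pur↔pur or pyr↔pyr)."""
    return a != b and ((a in PURINES) == (b in PURINES))


def _pair_structure():
    """Boolean 61×61 matrices classifying single-nucleotide codon changes."""
    single = np.zeros((N_STATES, N_STATES), dtype=bool)
    ts = np.zeros_like(single)
    nonsyn = np.zeros_like(single)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            p = diffs[0]
            ts[i, j] = is_transition(ci[p], cj[p])
            nonsyn[i, j] = AA_OF_CODON[ci] != AA_OF_CODON[cj]
    return single, ts, nonsyn


SINGLE_DIFF, IS_TRANSITION, IS_NONSYN = _pair_structure()


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC ambiguity codes preserved)."""
    return str(Seq(seq).reverse_complement())


def translate(dna: str, table_id: int = DEFAULT_TABLE_ID) -> str:
    """Codon-wise translation; stops → '*', codons with ambiguity → 'X'.

    Trailing bases not filling a codon are ignored.
    """
    table = CodonTable.unambiguous_dna_by_id[table_id]
    out = []
    dna = dna.upper()
    for i in range(0, len(dna) - 2, 3):
        codon = dna[i:i + 3]
        if codon in table.stop_codons:
            out.append("*")
        else:
            out.append(table.forward_table.get(codon, "X"))
    return "".join(out)


def codon_indices(dna: str) -> np.ndarray:
    """Map a gap-free in-frame DNA string to sense-codon state indices (-1 = missing).

    Stops and codons containing gaps or ambiguity codes are encoded as -1.
    """
    n = len(dna) // 3
    out = np.full(n, -1, dtype=np.int64)
    dna = dna.upper()
    for k in range(n):
        out[k] = CODON_INDEX.get(dna[3 * k:3 * k + 3], -1)
    return out
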
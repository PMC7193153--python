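"""Canonical amino-acid alphabet.

The 20 residues are kept in the order used by the original empirical
substitution-model publications (and by PAML's ``.dat`` files):
A R N D C Q E G H I L K M F P S T W Y V.  Every matrix, partial-likelihood
vector and posterior vector in this package is indexed in this order.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ARNDCQEGHILKMFPSTWYV"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Characters treated as missing data in alignments (marginalized in the
#: likelihood, never a 21st state).
MISSING: frozenset[str] = frozenset({"-", "X", "?"})

N_STATES: int = 20


def is_valid_state(ch: str) -> bool:
    return ch in AA_INDEX


def state_index(ch: str) -> int:
    """Index of a residue in the canonical order; raises for non-residues."""
    try:
        return AA_INDEX[ch]
    except KeyError:
        raise ValueError(f"{ch!r} is not one of the 20 canonical amino acids")
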
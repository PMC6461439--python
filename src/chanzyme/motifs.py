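"""Nudix-box and pore-motif location and classification.

Nudix hydrolases carry a conserved hexamer, the Nudix box (consensus
REUXEE, U hydrophobic), at the core of the active site.  A hexamer is
classified *canonical* (catalysis-competent) when the three conserved
glutamates (positions 2, 5 and 6) are present and position 3 is
hydrophobic; substitutions at those positions make it *vestigial*.  The
position-1 arginine is not required: active domains with an alanine
there are known.

The pore classification looks at the selectivity-filter segment and the
three-residue post-filter helix: invertebrate-like pores have a
phenylalanine immediately before an acidic post-filter triplet and a
glutamate in the filter; vertebrate-like pores have a proline prefix and
an uncharged triplet.  These substitutions track with channel
inactivation.  Classification is rule-based on user-supplied windows;
no alignment is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import SeqIO

__all__ = [
    "HYDROPHOBIC",
    "MotifReport",
    "read_fasta",
    "find_nudix_box",
    "classify_nudix",
    "classify_pore",
    "scan_sequences",
]

HYDROPHOBIC = frozenset("AILMFVWY")
ACIDIC = frozenset("DE")
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
NUDIX_CONSENSUS = "REUXEE"  # U = hydrophobic, X = any


@dataclass
class MotifReport:
    sequence_id: str
    nudix_position: int | None  # 1-based start of the hexamer
    nudix_hexamer: str | None
    nudix_score: int
    nudix_class: str | None  # "canonical" | "vestigial"
    pore_prefix: str | None = None
    postfilter_triplet: str | None = None
    acidic_count: int | None = None
    filter_glutamate: bool | None = None
    pore_class: str | None = None  # "invertebrate-like" | "vertebrate-like" | "ambiguous"


def read_fasta(path) -> dict[str, str]:
    """id -> uppercase amino-acid sequence; rejects non-amino-acid
    characters, naming the record and 1-based offset."""
    import warnings

    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for i, ch in enumerate(seq):
            if ch not in AMINO_ACIDS:
                raise ValueError(
                    f"record {rec.id!r}: invalid amino-acid character {ch!r} at position {i + 1}")
        sequences[rec.id] = seq
    if not sequences:
        warnings.warn(f"no FASTA records found in {path}")
    return sequences


def _score_window(window: str) -> int:
    """Score a hexamer against REUXEE: +1 identity at 1, 2, 5, 6; +1
    hydrophobic at 3; position 4 is a wildcard.  Maximum 5."""
    score = 0
    for idx, consensus in ((0, "R"), (1, "E"), (4, "E"), (5, "E")):
        if window[idx] == consensus:
            score += 1
    if window[2] in HYDROPHOBIC:
        score += 1
    return score


def find_nudix_box(sequence: str) -> tuple[int, str, int] | None:
    """Best-scoring hexamer window against the Nudix consensus.

    Returns (1-based position, hexamer, score); ties go to the smallest
    position.  Returns None when every window scores zero.
    """
    sequence = sequence.upper()
    if len(sequence) < 6:
        raise ValueError("sequence shorter than a hexamer")
    best_pos, best_score = -1, 0
    for i in range(len(sequence) - 5):
        s = _score_window(sequence[i:i + 6])
        if s > best_score:
            best_pos, best_score = i, s
    if best_pos < 0:
        return None
    return best_pos + 1, sequence[best_pos:best_pos + 6], best_score


def classify_nudix(hexamer: str) -> str:
    """"canonical" iff E at positions 2, 5 and 6 and a hydrophobic
    residue at position 3; otherwise "vestigial"."""
    hexamer = hexamer.upper()
    if len(hexamer) != 6:
        raise ValueError("Nudix box must be exactly 6 residues")
    ok = (hexamer[1] == "E" and hexamer[4] == "E" and hexamer[5] == "E"
          and hexamer[2] in HYDROPHOBIC)
    return "canonical" if ok else "vestigial"


def classify_pore(filter_segment: str, postfilter_segment: str) -> dict:
    """Pore classification from the filter and post-filter windows.

    `postfilter_segment` must contain at least 4 residues: the prefix
    residue followed by the three-residue post-filter triplet.
    """
    filter_segment = filter_segment.upper()
    postfilter_segment = postfilter_segment.upper()
    if len(postfilter_segment) < 4:
        raise ValueError("post-filter window must contain prefix + triplet (>= 4 residues)")
    if len(filter_segment) < 1:
        raise ValueError("filter window must contain at least 1 residue")
    prefix = postfilter_segment[0]
    triplet = postfilter_segment[1:4]
    acidic = sum(1 for ch in triplet if ch in ACIDIC)
    has_glu = "E" in filter_segment
    if prefix == "F" and acidic >= 2 and has_glu:
        pore_class = "invertebrate-like"
    elif prefix == "P" and acidic <= 1:
        pore_class = "vertebrate-like"
    else:
        pore_class = "ambiguous"
    return {
        "pore_prefix": prefix,
        "postfilter_triplet": triplet,
        "acidic_count": acidic,
        "filter_glutamate": has_glu,
        "pore_class": pore_class,
    }


def scan_sequences(sequences: dict[str, str],
                   pore_windows: dict[str, tuple[str, str]] | None = None
                   ) -> list[MotifReport]:
    """Scan each sequence for its Nudix box; classify the pore where
    windows (filter_segment, postfilter_segment) are supplied."""
    reports = []
    for seq_id, seq in sequences.items():
        hit = find_nudix_box(seq)
        if hit is None:
            rep = MotifReport(seq_id, None, None, 0, None)
        else:
            pos, hexamer, score = hit
            rep = MotifReport(seq_id, pos, hexamer, score, classify_nudix(hexamer))
        if pore_windows and seq_id in pore_windows:
            rep.__dict__.update(classify_pore(*pore_windows[seq_id]))
        reports.append(rep)
    return reports
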
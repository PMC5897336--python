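"""G2-box GXGXG motif scanning and hot-spot tabulation.

The sensor-kinase catalytic (CA) domain carries a glycine-rich G2 box
whose second position — the residue between the first two glycines — is a
phosphatase "hot spot": substitutions there retune the detection threshold
of the parent two-component system.  This module scans protein sequences
for the literal G.G.G pattern (which enforces presence of G1, G3 and G5),
tabulates the distribution of hot-spot residues across a protein set, and
annotates residues with Kyte-Doolittle hydropathy (functional hot-spot
substitutions are predominantly hydrophobic).

Positions are 1-based protein coordinates throughout, so a hit whose motif
starts at 626 has its hot spot at 627 (the TtrS L627 / ThsS L547
convention).  Upstream domain-architecture filtering is out of scope; a
caller-supplied ``search_start`` stands in for the "C-terminal to the
HisKA domain" constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

from Bio import SeqIO

__all__ = [
    "CANONICAL_AA",
    "KYTE_DOOLITTLE",
    "ProteinRecord",
    "MotifHit",
    "HotspotTally",
    "read_fasta",
    "find_g2_motifs",
    "tabulate_hotspots",
    "hydropathy_score",
]

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Kyte & Doolittle hydropathy scale (positive = hydrophobic)
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence; uppercase canonical alphabet (plus X) enforced."""

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.identifier}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - set(CANONICAL_AA + "X")
        if bad:
            raise ValueError(
                f"{self.identifier}: non-canonical letters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class MotifHit:
    start: int              # 1-based position of the first G
    motif: str              # the 5-residue window
    hotspot_residue: str    # motif[1], the second G2-box position
    hotspot_position: int   # start + 1, in protein coordinates


@dataclass
class HotspotTally:
    counts: dict[str, int]
    frequencies: dict[str, float]
    n_sequences_with_motif: int
    n_sequences_total: int


def read_fasta(path) -> list[ProteinRecord]:
    return [ProteinRecord(rec.id, str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def find_g2_motifs(record: ProteinRecord, search_start: int = 1) -> list[MotifHit]:
    """All (overlapping) GXGXG windows at or after ``search_start`` (1-based).

    A window qualifies when positions 1, 3 and 5 are all glycine — the
    G1/G3/G5 presence rule.  Sequences shorter than 5 residues simply
    yield no hits.
    """
    seq = record.sequence
    if not 1 <= search_start <= max(len(seq), 1):
        raise ValueError(
            f"search_start {search_start} outside sequence of length {len(seq)}")
    hits = []
    for i in range(search_start - 1, len(seq) - 4):
        if seq[i] == "G" and seq[i + 2] == "G" and seq[i + 4] == "G":
            hits.append(MotifHit(
                start=i + 1,
                motif=seq[i:i + 5],
                hotspot_residue=seq[i + 1],
                hotspot_position=i + 2,
            ))
    return hits


def tabulate_hotspots(
    records: Iterable[ProteinRecord],
    per_sequence: Literal["first", "all"] = "first",
    search_starts: Mapping[str, int] | None = None,
) -> HotspotTally:
    """Frequency table of hot-spot residues across a protein set.

    By default counts one hit per sequence (the first motif in the search
    region — SKs carry a single CA domain); ``per_sequence="all"`` counts
    every overlapping window.  ``search_starts`` maps identifiers to
    per-protein domain boundaries.
    """
    records = list(records)
    if not records:
        raise ValueError("empty record list")
    counts: dict[str, int] = {}
    n_with = 0
    for rec in records:
        start = (search_starts or {}).get(rec.identifier, 1)
        hits = find_g2_motifs(rec, start)
        if not hits:
            continue
        n_with += 1
        for hit in hits if per_sequence == "all" else hits[:1]:
            counts[hit.hotspot_residue] = counts.get(hit.hotspot_residue, 0) + 1
    total = sum(counts.values())
    freqs = {aa: c / total for aa, c in counts.items()} if total else {}
    return HotspotTally(counts, freqs, n_with, len(records))


def hydropathy_score(residue: str) -> float:
    """Kyte-Doolittle hydropathy of a canonical residue (higher = more hydrophobic)."""
    try:
        return KYTE_DOOLITTLE[residue.upper()]
    except KeyError:
        raise ValueError(f"no hydropathy score for residue {residue!r}") from None
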
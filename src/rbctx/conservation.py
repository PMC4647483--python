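"""Seed-aware cross-species conservation of mature miRNA sequences.

A mature miRNA counts as conserved in a species when its orthologous
region contains an ungapped window, in forward orientation, with zero
mismatches in the seed (nucleotides 2–8 of the mature sequence) and at
most one mismatch elsewhere.  T and U are interchangeable.  The default
panel is six vertebrates — human, chimp, rhesus, dog, mouse, zebrafish —
with {human, chimp, rhesus} as the primate subset; a call is
*primate-only* when every conserved species is a primate.  Because the
human region contains the exact mature sequence by construction, the
species count is always at least 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "DEFAULT_PANEL",
    "PRIMATES",
    "SpeciesSequenceSet",
    "WindowMatch",
    "ConservationCall",
    "seed_positions",
    "is_conserved_in_species",
    "conservation_call",
    "summarize_conservation",
]

DEFAULT_PANEL = ("human", "chimp", "rhesus", "dog", "mouse", "zebrafish")
PRIMATES = frozenset({"human", "chimp", "rhesus"})

_VALID = set("ACGTU")


def _to_rna(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq.replace("T", "U")


def seed_positions(mature_length: int) -> set[int]:
    """Seed positions (1-based): always nucleotides 2–8 of the mature sequence."""
    if mature_length < 8:
        raise ValueError(f"mature sequence of length {mature_length} has no full seed")
    return set(range(2, 9))


@dataclass(frozen=True)
class WindowMatch:
    """Best qualifying or near-qualifying window found in one region."""

    position: int  # 0-based offset of the window in the region
    mismatches: tuple[int, ...]  # 1-based mature positions that differ

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)


@dataclass(frozen=True)
class SpeciesSequenceSet:
    """One mature miRNA and its orthologous region per species."""

    mir_id: str
    mature_sequence: str
    regions: Mapping[str, str]  # species -> nucleotide string
    panel: tuple[str, ...] = DEFAULT_PANEL

    def __post_init__(self) -> None:
        mature = _to_rna(self.mature_sequence)
        for species in self.panel:
            if species not in self.regions:
                raise ValueError(f"{self.mir_id}: missing region for {species}")
            if len(self.regions[species]) < len(mature):
                raise ValueError(
                    f"{self.mir_id}: {species} region shorter than the mature sequence"
                )
        if "human" in self.panel and mature not in _to_rna(self.regions["human"]):
            raise ValueError(f"{self.mir_id}: human region lacks the exact mature sequence")


def is_conserved_in_species(
    mature: str, region: str
) -> tuple[bool, WindowMatch | None]:
    """Scan every ungapped window of the region for a qualifying match.

    A window qualifies with 0 seed mismatches and <= 1 mismatch outside
    the seed.  Returns the conserved flag and the best window (fewest
    total mismatches, leftmost on ties) among qualifying windows, or the
    overall best window when none qualifies (None only for an empty scan,
    which the length precondition excludes).
    """
    mature_rna = _to_rna(mature)
    region_rna = _to_rna(region)
    m = len(mature_rna)
    if len(region_rna) < m:
        raise ValueError("region shorter than mature sequence")
    seed = seed_positions(m)
    best_qualifying: WindowMatch | None = None
    best_any: WindowMatch | None = None
    for offset in range(len(region_rna) - m + 1):
        window = region_rna[offset : offset + m]
        mismatches = tuple(
            pos for pos in range(1, m + 1) if window[pos - 1] != mature_rna[pos - 1]
        )
        match = WindowMatch(position=offset, mismatches=mismatches)
        if best_any is None or match.n_mismatches < best_any.n_mismatches:
            best_any = match
        seed_mm = sum(1 for pos in mismatches if pos in seed)
        nonseed_mm = len(mismatches) - seed_mm
        if seed_mm == 0 and nonseed_mm <= 1:
            if best_qualifying is None or match.n_mismatches < best_qualifying.n_mismatches:
                best_qualifying = match
    if best_qualifying is not None:
        return True, best_qualifying
    return False, best_any


@dataclass(frozen=True)
class ConservationCall:
    mir_id: str
    conserved_in: frozenset[str]
    panel: tuple[str, ...]

    @property
    def species_count(self) -> int:
        return len(self.conserved_in)

    @property
    def bin(self) -> str:
        return "1-3" if self.species_count <= 3 else "4-6"

    @property
    def primate_only(self) -> bool:
        return self.conserved_in <= PRIMATES


def conservation_call(sequence_set: SpeciesSequenceSet) -> ConservationCall:
    """Per-species conservation flags, species count, bin, primate-only flag."""
    conserved = frozenset(
        species
        for species in sequence_set.panel
        if is_conserved_in_species(
            sequence_set.mature_sequence, sequence_set.regions[species]
        )[0]
    )
    call = ConservationCall(
        mir_id=sequence_set.mir_id, conserved_in=conserved, panel=sequence_set.panel
    )
    assert call.species_count >= 1, "human self-match guarantees count >= 1"
    return call


def summarize_conservation(
    calls_by_status: Mapping[str, Sequence[ConservationCall]]
) -> pd.DataFrame:
    """Percentage of calls per species-count bin and primate-only, by status.

    Bin percentages sum to 100 per status; primate_only is reported
    alongside (it overlaps the 1-3 bin, it is not a third bin).
    """
    rows = {}
    for status, calls in calls_by_status.items():
        if not calls:
            continue
        n = len(calls)
        rows[status] = {
            "pct_1_3": 100 * sum(c.bin == "1-3" for c in calls) / n,
            "pct_4_6": 100 * sum(c.bin == "4-6" for c in calls) / n,
            "pct_primate_only": 100 * sum(c.primate_only for c in calls) / n,
            "n": n,
        }
    return pd.DataFrame(rows).T
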
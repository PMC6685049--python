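"""Core domain types for the dimethylation-TAILS pipeline.

Residue coordinates are 1-based inclusive throughout (UniProt convention).
A cleavage site is denoted P1|P1', where P1' is the first residue of the
observed peptide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence, Tuple

#: The 20 canonical amino acids. Ambiguity codes (B, J, O, U, X, Z) are
#: rejected at parse time because downstream mass and motif arithmetic
#: assumes this alphabet.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class FormatError(ValueError):
    """Malformed input file or record."""


class ConfigurationError(ValueError):
    """Missing or inconsistent configuration (column mapping, design...)."""


def validate_sequence(seq: str, context: str = "sequence") -> str:
    """Return ``seq`` uppercased after checking the 20-letter alphabet."""
    if not seq:
        raise FormatError(f"empty {context}")
    seq = seq.upper()
    bad = set(seq) - _AA_SET
    if bad:
        raise FormatError(
            f"{context} contains non-standard residues {sorted(bad)}: {seq!r}"
        )
    return seq


Range = Tuple[int, int]  # 1-based inclusive


@dataclass
class ProteinAnnotation:
    """A protein sequence plus processing annotation.

    ``transit_peptide`` is the mitochondrial presequence (mtTP); when present
    it starts at residue 1 and its removal defines the mature N-terminus at
    ``transit_peptide[1] + 1``.  ``in_reference_set`` flags membership of the
    mitochondrial reference inventory (MitoCarta-like).
    """

    accession: str
    sequence: str
    has_initiator_met: bool = True
    transit_peptide: Optional[Range] = None
    chain: Optional[Range] = None
    propeptides: Sequence[Range] = field(default_factory=tuple)
    in_reference_set: bool = False

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence, f"sequence of {self.accession}")
        n = len(self.sequence)
        for name, rng in [("transit_peptide", self.transit_peptide), ("chain", self.chain)]:
            if rng is not None:
                self._check_range(rng, n, name)
        for rng in self.propeptides:
            self._check_range(rng, n, "propeptide")
        if self.transit_peptide is not None and self.transit_peptide[0] != 1:
            raise ValueError(
                f"{self.accession}: transit peptide must start at residue 1, "
                f"got {self.transit_peptide}"
            )
        if self.transit_peptide is not None and self.chain is not None:
            if self.chain[0] != self.transit_peptide[1] + 1:
                raise ValueError(
                    f"{self.accession}: chain start {self.chain[0]} != "
                    f"transit peptide end {self.transit_peptide[1]} + 1"
                )

    def _check_range(self, rng: Range, n: int, name: str) -> None:
        start, end = rng
        if not (1 <= start <= end <= n):
            raise ValueError(
                f"{self.accession}: {name} range {rng} outside [1, {n}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class Stage(str, Enum):
    """Sample stage relative to the polymer negative selection."""

    PREsel = "PREsel"
    POSTsel = "POSTsel"


class NTermMod(str, Enum):
    """N-terminal modification state of an identified peptide."""

    dimethyl_light = "dimethyl_light"
    dimethyl_heavy = "dimethyl_heavy"
    free = "free"


class Condition(str, Enum):
    CTRL = "CTRL"
    DA = "DA"


@dataclass
class PeptideObservation:
    """One identified peptide with its per-channel XIC areas.

    Missing areas are ``None`` (never coerced to 0: a zero XIC means
    not-detected and is likewise treated as missing downstream).
    """

    sequence: str
    accession: str = ""
    replicate_id: str = ""
    stage: Stage = Stage.POSTsel
    nterm_mod: NTermMod = NTermMod.dimethyl_light
    fixed_mods: Sequence[Tuple[int, float]] = field(default_factory=tuple)
    area_light: Optional[float] = None
    area_heavy: Optional[float] = None
    psm_count: int = 1

    def __post_init__(self) -> None:
        self.sequence = validate_sequence(self.sequence, "peptide sequence")
        for area, name in [(self.area_light, "area_light"), (self.area_heavy, "area_heavy")]:
            if area is not None and (math.isnan(area) or area < 0):
                raise ValueError(f"{name} must be non-negative or None, got {area}")
        if self.psm_count < 1:
            raise ValueError("psm_count must be a positive integer")

    @property
    def quantified(self) -> bool:
        return self.area_light is not None or self.area_heavy is not None


@dataclass(frozen=True)
class ReplicateLabeling:
    """Light/heavy channel orientation of one biological replicate."""

    replicate_id: str
    light_condition: Condition
    heavy_condition: Condition

    def __post_init__(self) -> None:
        if self.light_condition == self.heavy_condition:
            raise ConfigurationError(
                f"replicate {self.replicate_id}: light and heavy conditions "
                "must differ"
            )


@dataclass
class StudyDesign:
    """Label-swap design: channel orientation per biological replicate."""

    replicates: Sequence[ReplicateLabeling]

    def __post_init__(self) -> None:
        ids = [r.replicate_id for r in self.replicates]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("replicate ids must be unique")

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def replicate_ids(self) -> list[str]:
        return [r.replicate_id for r in self.replicates]

    def orientation(self, replicate_id: str) -> ReplicateLabeling:
        for r in self.replicates:
            if r.replicate_id == replicate_id:
                return r
        raise ConfigurationError(f"replicate {replicate_id!r} not in study design")

    def swapped(self) -> "StudyDesign":
        """Design with every light/heavy orientation flipped."""
        return StudyDesign(
            [
                ReplicateLabeling(r.replicate_id, r.heavy_condition, r.light_condition)
                for r in self.replicates
            ]
        )


def default_design(n_replicates: int = 7) -> StudyDesign:
    """Label-swap design over ``n_replicates`` biological replicates.

    The first ceil(n/2) replicates label CTRL light / DA heavy; the rest are
    swapped, ruling out any systematic labeling-efficiency bias.
    """
    reps = []
    for i in range(n_replicates):
        if i < (n_replicates + 1) // 2:
            reps.append(ReplicateLabeling(f"R{i + 1}", Condition.CTRL, Condition.DA))
        else:
            reps.append(ReplicateLabeling(f"R{i + 1}", Condition.DA, Condition.CTRL))
    return StudyDesign(reps)


@dataclass
class FilterConfig:
    """Significance thresholds for the differential analysis.

    The fold-change gate (default 1.5x, i.e. |mean log2| >= 0.58) applies to
    the mean per-replicate log2(DA/CTRL); at most ``max_missing`` of the
    replicates may lack a ratio.
    """

    fold_change_threshold: float = 1.5
    log2_threshold: Optional[float] = None
    p_threshold: float = 0.05
    max_missing: int = 2

    def __post_init__(self) -> None:
        if self.fold_change_threshold <= 0:
            raise ConfigurationError("fold_change_threshold must be positive")
        expected = math.log2(self.fold_change_threshold)
        if self.log2_threshold is None:
            self.log2_threshold = expected
        elif abs(self.log2_threshold - expected) > 1e-9:
            raise ConfigurationError(
                f"log2_threshold {self.log2_threshold} != "
                f"log2(fold_change_threshold) = {expected}"
            )
        if self.max_missing < 0:
            raise ConfigurationError("max_missing must be non-negative")

    def validate_against(self, design: StudyDesign) -> None:
        if self.max_missing >= design.n_replicates:
            raise ConfigurationError(
                f"max_missing {self.max_missing} must be smaller than the "
                f"number of replicates {design.n_replicates}"
            )
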
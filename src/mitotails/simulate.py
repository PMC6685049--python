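"""Synthetic TAILS experiments with known ground truth.

The generator emulates the wet-lab workflow end to end: a proteome in which
a configurable fraction of proteins carries a mitochondrial transit peptide,
motif-driven processing at the presequence end (with optional aminopeptidase
ragging) and at internal cleavage sites, amine blocking by dimethylation,
ArgC-like digestion (cleavage after R only; lysines are dimethyl-blocked and
therefore uncut) with up to three missed cleavages and a semi-specific
N-terminal peptide, stochastic polymer capture of free tryptic peptides,
log-normal MS1 areas with injected condition fold-changes, a label-swap
replicate design, and missing values.

Every emitted observation is traceable to a :class:`GroundTruth` record, so
the real pipeline can be scored against the simulation truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .types import (
    AMINO_ACIDS,
    Condition,
    NTermMod,
    PeptideObservation,
    ProteinAnnotation,
    Stage,
    StudyDesign,
    default_design,
    validate_sequence,
)

#: Rough human proteome residue frequencies (normalized at use).
RESIDUE_FREQUENCIES: Dict[str, float] = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.053, "V": 0.060, "W": 0.011, "Y": 0.027,
}

#: Cleavage-consensus injected at every true processing site:
#: slot -> (residue, probability).  Matches an Arg-Arg-Arg | Ala-Ser motif.
DEFAULT_CLEAVAGE_MOTIF: Dict[str, Tuple[str, float]] = {
    "P3": ("R", 0.6),
    "P2": ("R", 0.6),
    "P1": ("R", 0.6),
    "P1'": ("A", 0.6),
    "P2'": ("S", 0.6),
}


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic TAILS experiment."""

    n_proteins: int = 150
    length_range: Tuple[int, int] = (120, 600)
    fraction_mitochondrial: float = 0.3
    tp_length_range: Tuple[int, int] = (15, 60)
    cleavage_motif: Mapping[str, Tuple[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLEAVAGE_MOTIF)
    )
    ragging_probability: float = 0.2
    ragging_max_shift: int = 1
    internal_rate: float = 0.5  # mean internal cleavage sites per protein
    n_replicates: int = 7
    retention_probability: float = 0.85  # polymer capture prob per free peptide
    blocked_retention: float = 1.0  # survival prob of blocked N-term peptides
    area_log_mean: float = math.log(1e6)
    area_log_sigma: float = 1.2  # protein-abundance spread (natural log)
    replicate_sigma_log2: float = 0.3  # per-channel replicate noise (log2)
    effects: Sequence[Tuple[float, int]] = ((1.5, 15), (2.0, 15), (0.5, 15))
    n_da_only: int = 8
    n_ctrl_only: int = 8
    missing_rate: float = 0.1
    max_missed: int = 3
    min_peptide_length: int = 6
    max_peptide_length: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.fraction_mitochondrial,
            self.ragging_probability,
            self.retention_probability,
            self.blocked_retention,
            self.missing_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for _, prob in self.cleavage_motif.values():
            if not 0.0 <= prob <= 1.0:
                raise ValueError("motif probabilities must be in [0, 1]")


@dataclass
class ProteinTruth:
    accession: str
    is_mitochondrial: bool
    tp_end: Optional[int]  # last residue of the transit peptide
    mature_start: int  # canonical mature N-terminus (before ragging)
    internal_sites: Tuple[int, ...] = ()


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    proteins: Dict[str, ProteinTruth] = field(default_factory=dict)
    fold_change: Dict[str, float] = field(default_factory=dict)  # per peptide
    da_only: set = field(default_factory=set)
    ctrl_only: set = field(default_factory=set)
    #: per replicate: free peptide sequence -> captured by the polymer?
    captured: Dict[str, Dict[str, bool]] = field(default_factory=dict)
    #: per replicate: blocked peptide sequence -> (accession, p1_prime, ragged shift)
    blocked_origin: Dict[str, Dict[str, Tuple[str, int, int]]] = field(
        default_factory=dict
    )


# ---------------------------------------------------------------------------
# Digestion

def digest(
    sequence: str, max_missed: int = 3, semi_nterm: bool = True
) -> List[Tuple[str, int, int]]:
    """ArgC-like in-silico digestion: (peptide, 1-based start, missed count).

    Cleavage strictly after R (dimethyl-blocked K is uncut); all peptides
    between consecutive cut sites with at most ``max_missed`` internal missed
    cleavages are enumerated.  The sequence start is itself a boundary, so
    the protein's (possibly neo-) N-terminal peptide is emitted regardless of
    the upstream residue — the semi-specific peptide TAILS observes.  With
    ``semi_nterm`` False those N-terminal spans are dropped unless the
    sequence is R-free.
    """
    sequence = validate_sequence(sequence)
    n = len(sequence)
    cuts = [0] + [i + 1 for i in range(n - 1) if sequence[i] == "R"] + [n]
    out = []
    for i in range(len(cuts) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(cuts))):
            missed = j - i - 1
            pep = sequence[cuts[i] : cuts[j]]
            if i == 0 and not semi_nterm and len(cuts) > 2:
                continue
            out.append((pep, cuts[i] + 1, missed))
    return out


def _first_tryptic(
    sequence: str, start: int, min_len: int, max_missed: int
) -> Optional[str]:
    """Shortest peptide from ``start`` (1-based) reaching ``min_len``."""
    for pep, s, missed in digest(sequence[start - 1 :], max_missed=max_missed):
        if s == 1 and len(pep) >= min_len:
            return pep
    return None


# ---------------------------------------------------------------------------
# Proteome generation

_MOTIF_OFFSETS = {  # slot -> offset of the residue relative to p1' (0 = P1')
    "P4": -4, "P3": -3, "P2": -2, "P1": -1,
    "P1'": 0, "P2'": 1, "P3'": 2, "P4'": 3,
}


def _implant_motif(
    seq: List[str], p1_prime0: int, motif: Mapping[str, Tuple[str, float]], rng
) -> None:
    """Write motif residues around a 0-based cleavage position, in place."""
    for slot, (residue, prob) in motif.items():
        pos = p1_prime0 + _MOTIF_OFFSETS[slot]
        if 0 <= pos < len(seq) and rng.random() < prob:
            seq[pos] = residue


def generate_proteome(
    config: SimulationConfig, seed: Optional[int] = None
) -> Tuple[Dict[str, ProteinAnnotation], GroundTruth]:
    """Random proteome with transit peptides and internal cleavage sites.

    Sequences are i.i.d. from a human-like residue frequency table and start
    with M.  Mitochondrial proteins get a transit peptide of uniform length
    in ``tp_length_range`` with the cleavage motif implanted at its end;
    internal sites (Poisson per protein) carry the same motif.  The proteome
    and truth are a pure function of (config, seed).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    aa = np.array(list(AMINO_ACIDS))
    freq = np.array([RESIDUE_FREQUENCIES[a] for a in aa])
    freq = freq / freq.sum()
    proteins: Dict[str, ProteinAnnotation] = {}
    truth = GroundTruth()
    for i in range(config.n_proteins):
        accession = f"SYN{i:04d}"
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = list(rng.choice(aa, size=length, p=freq))
        seq[0] = "M"
        is_mito = bool(rng.random() < config.fraction_mitochondrial)
        tp_end = None
        if is_mito:
            tp_end = int(
                rng.integers(config.tp_length_range[0], config.tp_length_range[1] + 1)
            )
            _implant_motif(seq, tp_end, config.cleavage_motif, rng)
        mature_start = tp_end + 1 if tp_end is not None else 1
        n_internal = int(rng.poisson(config.internal_rate))
        lo, hi = mature_start + 20, length - config.min_peptide_length - 10
        sites = []
        if hi > lo:
            for pos in sorted(rng.integers(lo, hi, size=n_internal).tolist()):
                _implant_motif(seq, pos - 1, config.cleavage_motif, rng)
                sites.append(int(pos))
        sequence = "".join(seq)
        proteins[accession] = ProteinAnnotation(
            accession=accession,
            sequence=sequence,
            has_initiator_met=True,
            transit_peptide=(1, tp_end) if tp_end is not None else None,
            chain=(tp_end + 1, length) if tp_end is not None else None,
            in_reference_set=is_mito,
        )
        truth.proteins[accession] = ProteinTruth(
            accession=accession,
            is_mitochondrial=is_mito,
            tp_end=tp_end,
            mature_start=mature_start,
            internal_sites=tuple(sites),
        )
    return proteins, truth


# ---------------------------------------------------------------------------
# Experiment simulation

@dataclass
class SimulatedExperiment:
    pre: List[PeptideObservation]
    post: List[PeptideObservation]
    design: StudyDesign
    truth: GroundTruth
    proteins: Dict[str, ProteinAnnotation]


def simulate_experiment(
    proteins: Mapping[str, ProteinAnnotation],
    truth: GroundTruth,
    config: SimulationConfig,
    seed: Optional[int] = None,
    design: Optional[StudyDesign] = None,
) -> SimulatedExperiment:
    """Simulate PREsel/POSTsel observation tables for a label-swap design.

    Blocked N-terminal peptides (mature and neo) survive the negative
    selection with probability ``blocked_retention``; each free tryptic
    peptide is captured by the polymer with probability
    ``retention_probability`` and otherwise leaks into POSTsel.  MS1 areas
    are log-normal around a per-peptide base with per-channel replicate
    noise; injected fold-changes and condition-only peptides follow
    ``effects``, ``n_da_only`` and ``n_ctrl_only``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    design = design or default_design(config.n_replicates)

    # --- enumerate observable peptides per protein --------------------------
    blocked_catalog: List[Tuple[str, str, int]] = []  # (peptide, accession, p1')
    free_catalog: List[Tuple[str, str]] = []  # (peptide, accession)
    base_area: Dict[str, float] = {}
    for accession in sorted(proteins):
        prot = proteins[accession]
        pt = truth.proteins[accession]
        protein_base = math.exp(
            rng.normal(config.area_log_mean, config.area_log_sigma)
        )
        starts = [pt.mature_start, *pt.internal_sites]
        blocked_seqs = set()
        for s in starts:
            pep = _first_tryptic(
                prot.sequence, s, config.min_peptide_length, config.max_missed
            )
            if pep is None or len(pep) > config.max_peptide_length:
                continue
            blocked_catalog.append((pep, accession, s))
            blocked_seqs.add(pep)
            base_area[pep] = protein_base * math.exp(rng.normal(0.0, 0.5))
        mature_seq = prot.sequence[pt.mature_start - 1 :]
        for pep, s, missed in digest(mature_seq, max_missed=0):
            if s == 1 or pep in blocked_seqs:
                continue
            if not config.min_peptide_length <= len(pep) <= config.max_peptide_length:
                continue
            free_catalog.append((pep, accession))
            base_area.setdefault(pep, protein_base * math.exp(rng.normal(0.0, 0.5)))

    # --- assign condition effects to blocked N-term peptides ----------------
    blocked_peps = sorted({pep for pep, _, _ in blocked_catalog})
    rng.shuffle(blocked_peps)
    cursor = 0
    for fold, count in config.effects:
        for pep in blocked_peps[cursor : cursor + count]:
            truth.fold_change[pep] = fold
        cursor += count
    truth.da_only.update(blocked_peps[cursor : cursor + config.n_da_only])
    cursor += config.n_da_only
    truth.ctrl_only.update(blocked_peps[cursor : cursor + config.n_ctrl_only])

    # --- per-replicate sampling --------------------------------------------
    pre: List[PeptideObservation] = []
    post: List[PeptideObservation] = []
    sigma = config.replicate_sigma_log2

    def _areas(pep: str) -> Tuple[Optional[float], Optional[float]]:
        fold = truth.fold_change.get(pep, 1.0)
        base = base_area[pep]
        ctrl = base * 2.0 ** rng.normal(0.0, sigma)
        da = base * fold * 2.0 ** rng.normal(0.0, sigma)
        if pep in truth.da_only:
            ctrl = None
        if pep in truth.ctrl_only:
            da = None
        return ctrl, da

    def _observe(pep, accession, ctrl, da, rid, stage, mod) -> PeptideObservation:
        orient = design.orientation(rid)
        if orient.light_condition is Condition.CTRL:
            light, heavy = ctrl, da
        else:
            light, heavy = da, ctrl
        return PeptideObservation(
            sequence=pep,
            accession=accession,
            replicate_id=rid,
            stage=stage,
            nterm_mod=mod,
            area_light=light,
            area_heavy=heavy,
        )

    for rid in design.replicate_ids:
        truth.captured[rid] = {}
        truth.blocked_origin[rid] = {}
        # ragging: the mature start of a transit-peptide protein may shift
        shifted_blocked: List[Tuple[str, str, int, int]] = []
        for pep, accession, p1 in blocked_catalog:
            pt = truth.proteins[accession]
            shift = 0
            if pt.tp_end is not None and p1 == pt.mature_start:
                if rng.random() < config.ragging_probability:
                    shift = int(rng.integers(1, config.ragging_max_shift + 1))
                    if rng.random() < 0.5:
                        shift = -shift
                    shifted = _first_tryptic(
                        proteins[accession].sequence,
                        p1 + shift,
                        config.min_peptide_length,
                        config.max_missed,
                    )
                    if shifted is not None and p1 + shift >= 1:
                        base_area.setdefault(shifted, base_area[pep])
                        shifted_blocked.append((shifted, accession, p1 + shift, shift))
                        continue
                    shift = 0
            shifted_blocked.append((pep, accession, p1, shift))

        for pep, accession, p1, shift in shifted_blocked:
            if rng.random() < config.missing_rate:
                continue
            ctrl, da = _areas(pep)
            if ctrl is None and da is None:
                continue
            obs = _observe(pep, accession, ctrl, da, rid, Stage.PREsel, NTermMod.dimethyl_light)
            pre.append(obs)
            truth.blocked_origin[rid][pep] = (accession, p1, shift)
            if rng.random() < config.blocked_retention:
                post.append(
                    _observe(pep, accession, ctrl, da, rid, Stage.POSTsel, NTermMod.dimethyl_light)
                )
        for pep, accession in free_catalog:
            if rng.random() < config.missing_rate:
                continue
            ctrl, da = _areas(pep)
            pre.append(_observe(pep, accession, ctrl, da, rid, Stage.PREsel, NTermMod.free))
            captured = bool(rng.random() < config.retention_probability)
            truth.captured[rid][pep] = captured
            if not captured:
                post.append(
                    _observe(pep, accession, ctrl, da, rid, Stage.POSTsel, NTermMod.free)
                )
    return SimulatedExperiment(pre=pre, post=post, design=design, truth=truth, proteins=proteins)


def simulate_study(config: SimulationConfig, seed: Optional[int] = None) -> SimulatedExperiment:
    """Generate a proteome and simulate a full experiment in one call."""
    base_seed = config.seed if seed is None else seed
    proteins, truth = generate_proteome(config, seed=base_seed)
    return simulate_experiment(proteins, truth, config, seed=base_seed + 1)
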
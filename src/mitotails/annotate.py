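"""Peptide-to-protein mapping and N-terminus classification.

Every observed N-terminal peptide is mapped onto its protein and its start
position (P1', 1-based) is classified against the processing annotation:

* ``natural`` — the peptide starts at residue 1 (unprocessed protein);
* ``met_removal`` — starts at residue 2 of a Met-initiated protein without a
  transit peptide (methionine aminopeptidase product);
* ``tp_removal`` — starts exactly at transit-peptide end + 1 (the mature
  N-terminus after presequence processing);
* ``ragging_tp_removal`` — within +/-2 residues of transit-peptide end + 1
  (aminopeptidase ragging around the canonical processing site);
* ``propeptide_removal`` — starts at an annotated propeptide end + 1;
* ``internal`` — any other position: a neo-N-terminus from an unannotated
  proteolytic cleavage;
* ``unmapped`` — the peptide is not a substring of any supplied protein.

Precedence is exactly the order above; transit-peptide logic outranks
Met-removal when both could apply (annotation-driven, configurable via
``ragging_max_shift``).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .types import ProteinAnnotation


class NTermCategory(str, Enum):
    natural = "natural"
    met_removal = "met_removal"
    tp_removal = "tp_removal"
    ragging_tp_removal = "ragging_tp_removal"
    propeptide_removal = "propeptide_removal"
    internal = "internal"
    unmapped = "unmapped"


#: Categories counted as proteolytic processing products.
PROCESSED_CATEGORIES = frozenset(
    {
        NTermCategory.tp_removal,
        NTermCategory.ragging_tp_removal,
        NTermCategory.propeptide_removal,
        NTermCategory.internal,
    }
)


@dataclass
class NTermCall:
    """Classification of one observed N-terminal peptide."""

    sequence: str
    accession: str
    p1_prime: int  # 1-based index of the peptide's first residue; 0 if unmapped
    category: NTermCategory
    shift: int = 0  # signed offset from the nearest annotated processing site
    ambiguous_mapping: bool = False


def map_peptide(
    sequence: str,
    proteins: Mapping[str, ProteinAnnotation],
    declared_accession: Optional[str] = None,
) -> List[Tuple[str, int]]:
    """All exact-substring placements of ``sequence``, as (accession, p1_prime).

    When ``declared_accession`` is given the search is restricted to it.
    Proteins are scanned in accession sort order and the leftmost occurrence
    within each protein comes first, so the first element is the primary,
    deterministic placement.  Returns [] when the peptide matches nowhere.
    """
    if declared_accession is not None:
        if declared_accession not in proteins:
            return []
        search = [proteins[declared_accession]]
    else:
        search = [proteins[a] for a in sorted(proteins)]
    hits: List[Tuple[str, int]] = []
    for prot in search:
        start = prot.sequence.find(sequence)
        while start != -1:
            hits.append((prot.accession, start + 1))
            start = prot.sequence.find(sequence, start + 1)
    return hits


def _annotated_sites(annotation: ProteinAnnotation) -> List[int]:
    """P1' positions of annotated processing events, for shift reporting."""
    sites = [1]
    if annotation.transit_peptide is not None:
        sites.append(annotation.transit_peptide[1] + 1)
    elif annotation.has_initiator_met and annotation.sequence[0] == "M":
        sites.append(2)
    for prop in annotation.propeptides:
        sites.append(prop[1] + 1)
    return sites


def classify_nterm(
    p1_prime: int,
    annotation: ProteinAnnotation,
    sequence: str = "",
    ragging_max_shift: int = 2,
    ambiguous_mapping: bool = False,
) -> NTermCall:
    """Classify a mapped N-terminus against the protein annotation."""
    n = len(annotation.sequence)
    if not (1 <= p1_prime <= n):
        raise ValueError(
            f"{annotation.accession}: p1_prime {p1_prime} outside [1, {n}]"
        )
    tp_end = (
        annotation.transit_peptide[1] if annotation.transit_peptide is not None else None
    )
    prop_sites = {p[1] + 1 for p in annotation.propeptides}

    if p1_prime == 1:
        category = NTermCategory.natural
    elif tp_end is not None and p1_prime == tp_end + 1:
        category = NTermCategory.tp_removal
    elif tp_end is not None and 1 <= abs(p1_prime - (tp_end + 1)) <= ragging_max_shift:
        category = NTermCategory.ragging_tp_removal
    elif p1_prime in prop_sites:
        category = NTermCategory.propeptide_removal
    elif (
        p1_prime == 2
        and tp_end is None
        and annotation.has_initiator_met
        and annotation.sequence[0] == "M"
    ):
        category = NTermCategory.met_removal
    else:
        category = NTermCategory.internal

    nearest = min(_annotated_sites(annotation), key=lambda s: abs(p1_prime - s))
    shift = p1_prime - nearest
    if category in (
        NTermCategory.natural,
        NTermCategory.tp_removal,
        NTermCategory.propeptide_removal,
        NTermCategory.met_removal,
    ):
        shift = 0
    elif category is NTermCategory.ragging_tp_removal:
        shift = p1_prime - (tp_end + 1)

    return NTermCall(
        sequence=sequence or annotation.sequence[p1_prime - 1 :],
        accession=annotation.accession,
        p1_prime=p1_prime,
        category=category,
        shift=shift,
        ambiguous_mapping=ambiguous_mapping,
    )


def call_nterm_peptides(
    peptides: Iterable[Tuple[str, Optional[str]]],
    proteins: Mapping[str, ProteinAnnotation],
    ragging_max_shift: int = 2,
) -> List[NTermCall]:
    """Map and classify a batch of (sequence, declared_accession) peptides.

    An unmappable peptide yields an ``unmapped`` call rather than an error.
    """
    calls = []
    for sequence, declared in peptides:
        hits = map_peptide(sequence, proteins, declared)
        if not hits:
            calls.append(
                NTermCall(
                    sequence=sequence,
                    accession=declared or "",
                    p1_prime=0,
                    category=NTermCategory.unmapped,
                )
            )
            continue
        accession, p1_prime = hits[0]
        calls.append(
            classify_nterm(
                p1_prime,
                proteins[accession],
                sequence=sequence,
                ragging_max_shift=ragging_max_shift,
                ambiguous_mapping=len(hits) > 1,
            )
        )
    return calls


@dataclass
class NovelTPCandidate:
    """A proposed transit-peptide removal site for an unannotated protein."""

    accession: str
    p1_prime: int
    nterm_peptide: str
    transit_peptide: Tuple[int, int]
    chain: Tuple[int, int]
    n_replicates: int


def propose_novel_tp(
    calls: Iterable[Tuple[NTermCall, str]],
    proteins: Mapping[str, ProteinAnnotation],
    min_replicates: int = 3,
    max_presequence_length: int = 100,
) -> List[NovelTPCandidate]:
    """Propose transit-peptide sites from recurrent internal N-termini.

    ``calls`` pairs each N-terminus call with the replicate it was seen in.
    A candidate is emitted for a mitochondrial-reference protein lacking an
    annotated transit peptide when the same internal N-terminus recurs in at
    least ``min_replicates`` replicates at a position no deeper than
    ``max_presequence_length``; the implied presequence is [1, p1'-1].
    """
    seen: Dict[Tuple[str, int], set] = defaultdict(set)
    peptide_at: Dict[Tuple[str, int], str] = {}
    for call, replicate_id in calls:
        if call.category is not NTermCategory.internal:
            continue
        annotation = proteins.get(call.accession)
        if annotation is None or annotation.transit_peptide is not None:
            continue
        if not annotation.in_reference_set:
            continue
        key = (call.accession, call.p1_prime)
        seen[key].add(replicate_id)
        peptide_at.setdefault(key, call.sequence)
    candidates = []
    for (accession, p1_prime), reps in sorted(seen.items()):
        if len(reps) < min_replicates:
            continue
        if p1_prime < 2 or p1_prime > max_presequence_length:
            continue
        candidates.append(
            NovelTPCandidate(
                accession=accession,
                p1_prime=p1_prime,
                nterm_peptide=peptide_at[(accession, p1_prime)],
                transit_peptide=(1, p1_prime - 1),
                chain=(p1_prime, len(proteins[accession].sequence)),
                n_replicates=len(reps),
            )
        )
    return candidates


def summarize_terminome(calls: Sequence[NTermCall]) -> Dict[str, object]:
    """Counts per category (a partition of the input) plus the processed fraction.

    fraction_processed = (tp_removal + ragging + propeptide + internal) /
    mapped calls; unmapped calls are reported separately and excluded from
    the denominator.
    """
    counts = Counter(call.category.value for call in calls)
    per_category = {cat.value: counts.get(cat.value, 0) for cat in NTermCategory}
    mapped = len(calls) - per_category["unmapped"]
    processed = sum(per_category[c.value] for c in PROCESSED_CATEGORIES)
    per_protein: Dict[str, Counter] = defaultdict(Counter)
    for call in calls:
        if call.category is not NTermCategory.unmapped:
            per_protein[call.accession][call.category.value] += 1
    return {
        "n_calls": len(calls),
        "counts": per_category,
        "n_mapped": mapped,
        "n_processed": processed,
        "fraction_processed": processed / mapped if mapped else float("nan"),
        "per_protein": {acc: dict(c) for acc, c in sorted(per_protein.items())},
    }
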
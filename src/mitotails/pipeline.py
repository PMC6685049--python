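"""End-to-end orchestration: from peptide tables to terminome reports.

``run_pipeline`` chains the full analysis: negative-selection recovery,
PRE/POST protein overlaps and mitochondrial-reference fractions,
differential quantification over the label-swap design, N-terminus
classification and novel transit-peptide proposal, cleavage-consensus motif
and protease ranking.  ``write_outputs`` materialises the standard TSV/JSON
output files.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import motif as motif_mod
from . import stats as stats_mod
from .annotate import (
    NTermCall,
    NTermCategory,
    NovelTPCandidate,
    PROCESSED_CATEGORIES,
    call_nterm_peptides,
    propose_novel_tp,
    summarize_terminome,
)
from .quant import DifferentialAbundance, DifferentialAbundanceResults
from .types import (
    FilterConfig,
    NTermMod,
    PeptideObservation,
    ProteinAnnotation,
    Stage,
    StudyDesign,
)


@dataclass
class PipelineResult:
    differential: DifferentialAbundanceResults
    nterm_calls: List[NTermCall]
    novel_tp: List[NovelTPCandidate]
    terminome_summary: Dict[str, object]
    differential_summary: Dict[str, object]
    recovery: Dict[str, object]
    overlaps: Dict[str, object]
    fractions: Optional[Dict[str, object]]
    coverage: Optional[float]
    pfm_counts: Optional[pd.DataFrame]
    pfm_probs: Optional[pd.DataFrame]
    information: Optional[pd.Series]
    consensus: Optional[str]
    protease_ranking: Optional[pd.DataFrame]
    windows: List[motif_mod.CleavageWindow] = field(default_factory=list)


def _by_replicate(
    observations: Sequence[PeptideObservation], stage: Stage
) -> Dict[str, set]:
    out: Dict[str, set] = defaultdict(set)
    for o in observations:
        if o.stage == stage:
            out[o.replicate_id].add(o.sequence)
    return dict(out)


def _protein_sets(
    observations: Sequence[PeptideObservation], stage: Stage
) -> Dict[str, set]:
    out: Dict[str, set] = defaultdict(set)
    for o in observations:
        if o.stage == stage and o.accession:
            out[o.replicate_id].add(o.accession)
    return dict(out)


def run_pipeline(
    observations: Sequence[PeptideObservation],
    proteins: Mapping[str, ProteinAnnotation],
    design: StudyDesign,
    config: Optional[FilterConfig] = None,
    profiles: Optional[Sequence[motif_mod.SpecificityProfile]] = None,
    min_replicates_novel_tp: int = 3,
    motif_min_freq: float = 0.2,
) -> PipelineResult:
    """Run the complete analysis on mixed PREsel/POSTsel observations."""
    config = config or FilterConfig()
    post = [o for o in observations if o.stage == Stage.POSTsel]

    # --- selection efficiency and protein-level statistics ------------------
    pre_pep = _by_replicate(observations, Stage.PREsel)
    post_pep = _by_replicate(observations, Stage.POSTsel)
    recovery = stats_mod.recovery_summary(pre_pep, post_pep) if pre_pep else {
        "per_replicate": {}, "mean": None, "sd": None,
    }
    pre_prot = _protein_sets(observations, Stage.PREsel)
    post_prot = _protein_sets(observations, Stage.POSTsel)
    pre_union = set().union(*pre_prot.values()) if pre_prot else set()
    post_union = set().union(*post_prot.values()) if post_prot else set()
    only_pre, only_post, both = stats_mod.set_overlap(pre_union, post_union)
    overlaps = {
        "n_pre": len(pre_union),
        "n_post": len(post_union),
        "only_pre": only_pre,
        "only_post": only_post,
        "both": both,
    }
    reference = {a for a, p in proteins.items() if p.in_reference_set}
    fractions = None
    cov = None
    if reference:
        if pre_prot and set(pre_prot) == set(post_prot) and len(pre_prot) >= 2:
            fractions = stats_mod.paired_fraction_test(pre_prot, post_prot, reference)
        cov = stats_mod.coverage(pre_union | post_union, reference)

    # --- differential quantification (POSTsel, blocked N-termini) -----------
    model = DifferentialAbundance(post, design, config=config)
    differential = model.fit()

    # --- N-terminus classification ------------------------------------------
    blocked = [o for o in post if o.nterm_mod != NTermMod.free]
    unique_peps = sorted({(o.sequence, o.accession or None) for o in blocked})
    calls = call_nterm_peptides(unique_peps, proteins)
    call_by_key = {(c.sequence, c.accession): c for c in calls}
    calls_with_reps: List[Tuple[NTermCall, str]] = []
    for o in blocked:
        c = call_by_key.get((o.sequence, o.accession)) or call_by_key.get(
            (o.sequence, "")
        )
        if c is None:
            for cand in calls:
                if cand.sequence == o.sequence:
                    c = cand
                    break
        if c is not None:
            calls_with_reps.append((c, o.replicate_id))
    novel = propose_novel_tp(
        calls_with_reps, proteins, min_replicates=min_replicates_novel_tp
    )
    terminome = summarize_terminome(calls)
    diff_summary = stats_mod.summarize_differential(differential.results, calls)

    # --- cleavage motif ------------------------------------------------------
    windows = [
        motif_mod.extract_window(proteins[c.accession], c.p1_prime)
        for c in calls
        if c.category in PROCESSED_CATEGORIES and c.accession in proteins
    ]
    pfm_counts = pfm_probs = information = None
    consensus_str = None
    ranking = None
    if windows:
        pfm_counts, pfm_probs = motif_mod.build_frequency_matrix(windows)
        information = motif_mod.information_content(pfm_probs)
        consensus_str = motif_mod.consensus(pfm_probs, min_freq=motif_min_freq)
        if profiles is None:
            profiles = motif_mod.load_packaged_profiles()
        ranking = motif_mod.rank_proteases(windows, profiles)

    return PipelineResult(
        differential=differential,
        nterm_calls=calls,
        novel_tp=novel,
        terminome_summary=terminome,
        differential_summary=diff_summary,
        recovery=recovery,
        overlaps=overlaps,
        fractions=fractions,
        coverage=cov,
        pfm_counts=pfm_counts,
        pfm_probs=pfm_probs,
        information=information,
        consensus=consensus_str,
        protease_ranking=ranking,
        windows=windows,
    )


def write_outputs(result: PipelineResult, out_dir) -> None:
    """Write the standard output files into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.differential.to_tsv(out / "differential.tsv")
    pd.DataFrame(
        [
            {
                "sequence": c.sequence,
                "accession": c.accession,
                "p1_prime": c.p1_prime,
                "category": c.category.value,
                "shift": c.shift,
                "ambiguous_mapping": int(c.ambiguous_mapping),
            }
            for c in result.nterm_calls
        ]
    ).to_csv(out / "nterm_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "accession": n.accession,
                "nterm_peptide": n.nterm_peptide,
                "p_prime_position": n.p1_prime,
                "mtTP": f"{n.transit_peptide[0]}-{n.transit_peptide[1]}",
                "chain": f"{n.chain[0]}-{n.chain[1]}",
                "n_replicates": n.n_replicates,
            }
            for n in result.novel_tp
        ]
    ).to_csv(out / "novel_tp.tsv", sep="\t", index=False)
    terminome_payload = {
        "recovery": result.recovery,
        "overlaps": result.overlaps,
        "reference_fractions": result.fractions,
        "coverage": result.coverage,
        **result.terminome_summary,
    }
    (out / "terminome_summary.json").write_text(
        json.dumps(terminome_payload, indent=2, default=str)
    )
    (out / "differential_summary.json").write_text(
        json.dumps(result.differential_summary, indent=2)
    )
    if result.pfm_counts is not None:
        result.pfm_counts.to_csv(out / "pfm.tsv", sep="\t")
        logo = pd.DataFrame(
            {
                "information_bits": result.information,
            }
        )
        for residue in result.pfm_probs.index:
            logo[residue] = (
                result.pfm_probs.loc[residue] * result.information
            )
        logo.to_csv(out / "logo_data.tsv", sep="\t")
        (out / "motif.json").write_text(
            json.dumps(
                {
                    "consensus": result.consensus,
                    "n_windows": len(result.windows),
                },
                indent=2,
            )
        )
    if result.protease_ranking is not None:
        result.protease_ranking.to_csv(
            out / "protease_ranking.tsv", sep="\t", index=False
        )
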
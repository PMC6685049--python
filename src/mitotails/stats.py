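"""Selection-efficiency and enrichment statistics for the terminome.

Recovery R = #unique POSTsel peptides / #unique PREsel peptides per
replicate; reference fractions use a mitochondrial reference inventory
(MitoCarta-like) and are compared between stages with a paired two-tailed
t-test on untransformed fractions.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats as sps

from .annotate import NTermCall, NTermCategory
from .quant import DifferentialClass, DifferentialResult
from .types import ConfigurationError


def recovery(pre_peptides: Iterable[str], post_peptides: Iterable[str]) -> Optional[float]:
    """Negative-selection recovery R = |unique POSTsel| / |unique PREsel|.

    Returns None (not-applicable) when the PREsel list is empty.
    """
    pre = set(pre_peptides)
    if not pre:
        return None
    return len(set(post_peptides)) / len(pre)


def recovery_summary(
    pre_by_replicate: Mapping[str, Iterable[str]],
    post_by_replicate: Mapping[str, Iterable[str]],
) -> Dict[str, object]:
    """Per-replicate R plus mean and SD across replicates with defined R."""
    per_rep: Dict[str, Optional[float]] = {}
    for rid in sorted(pre_by_replicate):
        per_rep[rid] = recovery(pre_by_replicate[rid], post_by_replicate.get(rid, ()))
    values = [v for v in per_rep.values() if v is not None]
    return {
        "per_replicate": per_rep,
        "mean": float(np.mean(values)) if values else None,
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else None,
    }


def set_overlap(proteins_a: Iterable[str], proteins_b: Iterable[str]) -> Tuple[int, int, int]:
    """(only_A, only_B, both) counts; the three always partition the union."""
    a, b = set(proteins_a), set(proteins_b)
    both = len(a & b)
    return len(a) - both, len(b) - both, both


def reference_fraction(proteins: Iterable[str], reference: Iterable[str]) -> float:
    """Fraction of the identified set belonging to the reference inventory."""
    s = set(proteins)
    if not s:
        return float("nan")
    return len(s & set(reference)) / len(s)


def paired_fraction_test(
    pre_sets: Mapping[str, Iterable[str]],
    post_sets: Mapping[str, Iterable[str]],
    reference: Iterable[str],
) -> Dict[str, object]:
    """Paired two-tailed t-test of reference fractions between two stages.

    Replicate ids must pair up.  Degenerate all-equal pairs give t = nan,
    p = 1 (no evidence of a difference).
    """
    if set(pre_sets) != set(post_sets):
        raise ConfigurationError(
            "paired test requires the same replicate ids in both stages"
        )
    if len(pre_sets) < 2:
        raise ConfigurationError("paired test requires at least two replicates")
    ref = set(reference)
    rids = sorted(pre_sets)
    pre = np.array([reference_fraction(pre_sets[r], ref) for r in rids])
    post = np.array([reference_fraction(post_sets[r], ref) for r in rids])
    diff = post - pre
    if np.ptp(diff) == 0.0 and diff[0] == 0.0:
        t, p = float("nan"), 1.0
    else:
        res = sps.ttest_rel(post, pre)
        t, p = float(res.statistic), float(res.pvalue)
        if math.isnan(p):  # zero-variance nonzero difference
            p = 0.0
    return {
        "replicates": rids,
        "fractions_pre": pre.tolist(),
        "fractions_post": post.tolist(),
        "mean_pre": float(pre.mean()),
        "mean_post": float(post.mean()),
        "t_statistic": t,
        "p_value": p,
    }


def coverage(identified_proteins: Iterable[str], reference: Iterable[str]) -> float:
    """Fraction of the reference inventory that was identified."""
    ref = set(reference)
    if not ref:
        raise ConfigurationError("reference set must be non-empty")
    return len(set(identified_proteins) & ref) / len(ref)


_OVER_CLUSTER = {DifferentialClass.over, DifferentialClass.da_only}
_UNDER_CLUSTER = {DifferentialClass.under, DifferentialClass.ctrl_only}


def summarize_differential(
    results: Sequence[DifferentialResult],
    calls: Sequence[NTermCall] = (),
) -> Dict[str, object]:
    """Cluster sizes and per-category breakdown of the differential list.

    The over cluster pools quantitative ``over`` with qualitative ``da_only``
    rows (and symmetrically for under).  N-terminus categories are joined on
    (sequence, accession) from ``calls``.
    """
    cat_by_key = {(c.sequence, c.accession): c.category for c in calls}
    clusters = {"over": [], "under": []}
    for r in results:
        if r.differential_class in _OVER_CLUSTER:
            clusters["over"].append(r)
        elif r.differential_class in _UNDER_CLUSTER:
            clusters["under"].append(r)

    def _breakdown(items: List[DifferentialResult]) -> Dict[str, int]:
        counts = {cat.value: 0 for cat in NTermCategory}
        for r in items:
            cat = cat_by_key.get((r.sequence, r.accession))
            if cat is not None:
                counts[cat.value] += 1
        return counts

    over_b, under_b = _breakdown(clusters["over"]), _breakdown(clusters["under"])
    accessions: Set[str] = {
        r.accession for cluster in clusters.values() for r in cluster
    }
    qualitative = sum(
        1
        for cluster in clusters.values()
        for r in cluster
        if r.differential_class in (DifferentialClass.da_only, DifferentialClass.ctrl_only)
    )
    return {
        "n_over": len(clusters["over"]),
        "n_under": len(clusters["under"]),
        "n_total": len(clusters["over"]) + len(clusters["under"]),
        "n_qualitative": qualitative,
        "n_distinct_proteins": len(accessions),
        "over_categories": over_b,
        "under_categories": under_b,
        "internal_total": over_b["internal"] + under_b["internal"],
        "ragging_over": over_b["ragging_tp_removal"],
        "ragging_under": under_b["ragging_tp_removal"],
    }
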
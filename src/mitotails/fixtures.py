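"""Packaged worked-example records and synthetic stand-in sequences.

The three packaged tables hold, verbatim, the published worked-example rows
of this workflow: two newly proposed transit-peptide removal sites, 24
N-terminal peptides over-represented under dopamine treatment and 37
under-represented ones.  ``load_paper_fixtures`` returns them exactly as
printed; converters re-express the rows as the package's own result types so
the summary statistics can be recomputed from them.

``synthetic_reference_proteins`` builds SYNTHETIC stand-in sequences for the
three reference proteins used in mapping examples: random backgrounds with
the published N-terminal peptides implanted at their published positions.
They reproduce lengths and peptide placements only, not the real sequences.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .annotate import NTermCall, NTermCategory
from .quant import DifferentialClass, DifferentialResult
from .types import AMINO_ACIDS, ProteinAnnotation

#: Printed N-terminus type strings -> classifier categories.
PRINTED_TYPE_TO_CATEGORY = {
    "Natural": NTermCategory.natural,
    "Met-removal": NTermCategory.met_removal,
    "TP-removal": NTermCategory.tp_removal,
    "TP-removal (new)": NTermCategory.tp_removal,
    "ragging TP-removal": NTermCategory.ragging_tp_removal,
    "Propeptide-removal": NTermCategory.propeptide_removal,
    "Internal": NTermCategory.internal,
}


def _read_table(name: str) -> pd.DataFrame:
    ref = resources.files("mitotails").joinpath(f"data/{name}")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_paper_fixtures() -> Dict[str, pd.DataFrame]:
    """The packaged worked-example tables, exactly as printed.

    Keys: ``table1`` (novel transit-peptide sites), ``table2``
    (over-represented, n=24), ``table3`` (under-represented, n=37).
    """
    return {
        "table1": _read_table("table1.tsv"),
        "table2": _read_table("table2.tsv"),
        "table3": _read_table("table3.tsv"),
    }


def fixture_nterm_calls(table: pd.DataFrame) -> List[NTermCall]:
    """Re-express the printed N-term type of each fixture row as an NTermCall.

    Positions are not printed for these rows, so ``p1_prime`` is left 0 and
    the shift is +/-1 for ragging rows (sign unknown from the table alone).
    """
    calls = []
    for _, row in table.iterrows():
        category = PRINTED_TYPE_TO_CATEGORY[row["nterm_type"]]
        calls.append(
            NTermCall(
                sequence=row["sequence"],
                accession=row["accession"],
                p1_prime=0,
                category=category,
                shift=1 if category is NTermCategory.ragging_tp_removal else 0,
            )
        )
    return calls


def fixture_differential_results(
    table: pd.DataFrame, cluster: str
) -> List[DifferentialResult]:
    """Re-express fixture rows as DifferentialResults.

    ``cluster`` is "over" or "under"; qualitative rows become
    ``da_only``/``ctrl_only`` per their printed flag.
    """
    if cluster not in ("over", "under"):
        raise ValueError("cluster must be 'over' or 'under'")
    out = []
    for _, row in table.iterrows():
        flag = row.get("qualitative", "").strip()
        if flag:
            cls = DifferentialClass.da_only if flag == "DA_only" else DifferentialClass.ctrl_only
            mean = sem = None
        else:
            cls = DifferentialClass.over if cluster == "over" else DifferentialClass.under
            mean = float(row["log2_mean"])
            sem = float(row["log2_sem"])
        out.append(
            DifferentialResult(
                sequence=row["sequence"],
                accession=row["accession"],
                n_observed=0 if flag else 5,
                mean_log2=mean,
                sem_log2=sem,
                differential_class=cls,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Synthetic stand-in reference sequences

#: (accession, length, implanted N-terminal peptide, its 1-based start,
#:  whether the protein is in the mitochondrial reference set)
_SYNTHETIC_SPECS: Tuple[Tuple[str, int, str, int, bool], ...] = (
    ("Q9BW92", 718, "LHTAVVSTPPR", 20, True),  # threonine--tRNA ligase-like
    ("P82673", 323, "STAVYSATPVPTPSLPER", 23, True),  # mt ribosomal S35-like
    ("P00403", 227, "LLDVDNR", 135, True),  # cytochrome c oxidase 2-like
)


def synthetic_reference_proteins(seed: int = 917) -> Dict[str, ProteinAnnotation]:
    """SYNTHETIC stand-ins for the mapping-example reference proteins.

    Each sequence is i.i.d. random with the published N-terminal peptide
    implanted so that its first residue sits at the published P1' position;
    the published protein length is preserved and the peptide occurs exactly
    once.  No transit peptide is annotated (these are the proteins whose
    presequences were unannotated), so recurrent observation of the implanted
    peptide proposes the transit peptide anew.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    out: Dict[str, ProteinAnnotation] = {}
    for accession, length, peptide, start, in_ref in _SYNTHETIC_SPECS:
        while True:
            seq = "".join(rng.choice(aa, size=length))
            seq = "M" + seq[1:]
            seq = seq[: start - 1] + peptide + seq[start - 1 + len(peptide) :]
            if seq.count(peptide) == 1 and len(seq) == length:
                break
        out[accession] = ProteinAnnotation(
            accession=accession,
            sequence=seq,
            has_initiator_met=True,
            in_reference_set=in_ref,
        )
    return out
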
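"""Readers and writers for the tabular and sequence formats of the pipeline.

All tables are tab-separated with a header row.  Residue ranges are written
"start-end", 1-based inclusive.  Missing XIC areas stay missing (empty cell),
never 0.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    Condition,
    ConfigurationError,
    FormatError,
    NTermMod,
    PeptideObservation,
    ProteinAnnotation,
    Range,
    ReplicateLabeling,
    Stage,
    StudyDesign,
    validate_sequence,
)

# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> List[ProteinAnnotation]:
    """Read protein sequences; annotation fields are left at their defaults.

    The accession is the first whitespace-delimited token of the header.
    Trailing '*' stop characters are stripped, sequences uppercased and
    validated against the 20-letter alphabet.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        seq = str(rec.seq).replace("*", "").upper()
        if not accession:
            raise FormatError(f"{path}: FASTA record with empty header")
        if not seq:
            raise FormatError(f"{path}: empty sequence for record {accession!r}")
        try:
            seq = validate_sequence(seq, f"sequence of {accession}")
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        records.append(ProteinAnnotation(accession=accession, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinAnnotation], path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Peptide tables

#: Default column mapping matching a PEAKS-like export.
DEFAULT_COLUMN_MAPPING: Dict[str, str] = {
    "sequence": "sequence",
    "accession": "accession",
    "replicate_id": "replicate",
    "stage": "stage",
    "nterm_mod": "nterm_mod",
    "area_light": "area_light",
    "area_heavy": "area_heavy",
    "psm_count": "psm_count",
}

_REQUIRED_COLUMNS = ("sequence", "replicate_id", "stage", "area_light", "area_heavy")


def read_peptide_table(
    path, column_mapping: Optional[Mapping[str, str]] = None
) -> List[PeptideObservation]:
    """Parse a search-engine peptide export into observations.

    Duplicate rows (same sequence/replicate/stage/mods) are retained for later
    aggregation.  Blank area cells are recorded as missing, never zero.
    """
    mapping = dict(DEFAULT_COLUMN_MAPPING)
    if column_mapping:
        mapping.update(column_mapping)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for field in _REQUIRED_COLUMNS:
        col = mapping.get(field)
        if col is None or col not in df.columns:
            raise ConfigurationError(
                f"{path}: required field {field!r} not resolvable "
                f"(mapped column {col!r} absent from header {list(df.columns)})"
            )
    observations = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        def _area(field: str) -> Optional[float]:
            raw = row[mapping[field]].strip()
            if raw == "" or raw.upper() in {"NA", "NAN"}:
                return None
            try:
                return float(raw)
            except ValueError:
                raise FormatError(
                    f"{path}, line {line_no}: non-numeric {field} value {raw!r}"
                ) from None

        kwargs = dict(
            sequence=row[mapping["sequence"]],
            replicate_id=row[mapping["replicate_id"]],
            stage=Stage(row[mapping["stage"]]),
            area_light=_area("area_light"),
            area_heavy=_area("area_heavy"),
        )
        acc_col = mapping.get("accession")
        if acc_col and acc_col in df.columns:
            kwargs["accession"] = row[acc_col]
        mod_col = mapping.get("nterm_mod")
        if mod_col and mod_col in df.columns and row[mod_col].strip():
            kwargs["nterm_mod"] = NTermMod(row[mod_col])
        psm_col = mapping.get("psm_count")
        if psm_col and psm_col in df.columns and row[psm_col].strip():
            kwargs["psm_count"] = int(row[psm_col])
        try:
            observations.append(PeptideObservation(**kwargs))
        except (ValueError, KeyError) as exc:
            raise FormatError(f"{path}, line {line_no}: {exc}") from exc
    return observations


def write_peptide_table(observations: Iterable[PeptideObservation], path) -> None:
    rows = []
    for o in observations:
        rows.append(
            {
                "sequence": o.sequence,
                "accession": o.accession,
                "replicate": o.replicate_id,
                "stage": o.stage.value,
                "nterm_mod": o.nterm_mod.value,
                "area_light": "" if o.area_light is None else repr(o.area_light),
                "area_heavy": "" if o.area_heavy is None else repr(o.area_heavy),
                "psm_count": o.psm_count,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotation tables

def _parse_range(raw: str, accession: str) -> Optional[Range]:
    raw = raw.strip()
    if not raw:
        return None
    # tolerate the en-dash used in printed tables
    raw = raw.replace("–", "-")
    try:
        start_s, end_s = raw.split("-")
        rng = (int(start_s), int(end_s))
    except ValueError:
        raise FormatError(
            f"annotation for {accession}: cannot parse range {raw!r} "
            "(expected 'start-end')"
        ) from None
    return rng


def read_annotation_table(
    path, sequences: Optional[Mapping[str, ProteinAnnotation]] = None
) -> Dict[str, ProteinAnnotation]:
    """Read per-protein processing annotation keyed by accession.

    Columns: accession, has_initiator_met (0/1), transit_peptide, chain,
    propeptides (';'-joined ranges), in_reference_set (0/1).  When
    ``sequences`` is supplied, ranges are validated against sequence length
    and the returned annotations carry the sequences; otherwise a placeholder
    sequence long enough for the ranges is attached.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "accession" not in df.columns:
        raise ConfigurationError(f"{path}: missing 'accession' column")
    out: Dict[str, ProteinAnnotation] = {}
    for _, row in df.iterrows():
        acc = row["accession"].strip()
        tp = _parse_range(row.get("transit_peptide", ""), acc)
        chain = _parse_range(row.get("chain", ""), acc)
        props = tuple(
            r
            for r in (
                _parse_range(part, acc)
                for part in row.get("propeptides", "").split(";")
                if part.strip()
            )
            if r is not None
        )
        if sequences is not None:
            if acc not in sequences:
                raise ConfigurationError(
                    f"{path}: accession {acc!r} has annotation but no sequence"
                )
            seq = sequences[acc].sequence
        else:
            max_end = max(
                [r[1] for r in [tp, chain, *props] if r is not None] + [1]
            )
            seq = "A" * max_end
        try:
            out[acc] = ProteinAnnotation(
                accession=acc,
                sequence=seq,
                has_initiator_met=row.get("has_initiator_met", "1").strip() != "0",
                transit_peptide=tp,
                chain=chain,
                propeptides=props,
                in_reference_set=row.get("in_reference_set", "0").strip() == "1",
            )
        except ValueError as exc:
            raise FormatError(f"{path}: invalid annotation for {acc}: {exc}") from exc
    return out


def write_annotation_table(annotations: Mapping[str, ProteinAnnotation], path) -> None:
    def _fmt(rng: Optional[Range]) -> str:
        return "" if rng is None else f"{rng[0]}-{rng[1]}"

    rows = [
        {
            "accession": a.accession,
            "has_initiator_met": int(a.has_initiator_met),
            "transit_peptide": _fmt(a.transit_peptide),
            "chain": _fmt(a.chain),
            "propeptides": ";".join(_fmt(r) for r in a.propeptides),
            "in_reference_set": int(a.in_reference_set),
        }
        for a in annotations.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Study design tables

def read_design_table(path) -> StudyDesign:
    """Read the label-swap design: replicate, light_condition, heavy_condition."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"replicate", "light_condition", "heavy_condition"}
    if not required <= set(df.columns):
        raise ConfigurationError(
            f"{path}: design table needs columns {sorted(required)}"
        )
    reps = [
        ReplicateLabeling(
            row["replicate"].strip(),
            Condition(row["light_condition"].strip()),
            Condition(row["heavy_condition"].strip()),
        )
        for _, row in df.iterrows()
    ]
    return StudyDesign(reps)


def write_design_table(design: StudyDesign, path) -> None:
    rows = [
        {
            "replicate": r.replicate_id,
            "light_condition": r.light_condition.value,
            "heavy_condition": r.heavy_condition.value,
        }
        for r in design.replicates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
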
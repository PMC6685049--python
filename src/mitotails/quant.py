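"""Dimethyl-label mass model and swap-aware differential quantification.

The quantitative core: per-replicate channel aggregation, orientation-aware
log2(DA/CTRL) ratios, the missing-value policy, and the per-peptide
differential classification are exposed both as free functions and as a
model/results pair (`DifferentialAbundance` / `DifferentialAbundanceResults`)
in the style of statsmodels.

Classification of one peptide across n replicates (default n=7):

* quantitative ``over``/``under``: at least n - max_missing replicate ratios,
  |mean log2| >= log2(1.5) = 0.58 and two-tailed one-sample t-test p < 0.05;
* qualitative ``da_only``/``ctrl_only``: detected exclusively in one
  condition in at least n - max_missing replicates, never in the other;
* otherwise ``not_significant`` or ``insufficient_data``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass
from scipy import stats as sps

from .types import (
    Condition,
    ConfigurationError,
    FilterConfig,
    PeptideObservation,
    Stage,
    StudyDesign,
    validate_sequence,
)

logger = logging.getLogger(__name__)

_H1 = _pmass.nist_mass["H"][1][0]
_H2 = _pmass.nist_mass["H"][2][0]
_C12 = _pmass.nist_mass["C"][12][0]
_C13 = _pmass.nist_mass["C"][13][0]
_WATER = _pmass.calculate_mass(formula="H2O")


class Isotope(str, Enum):
    light = "light"
    heavy = "heavy"


def dimethyl_mass_delta(isotope: Isotope | str) -> float:
    """Exact monoisotopic mass shift of double methylation of one amine.

    Light formaldehyde adds 2 x 12C and 4 x 1H (net +C2H4, 28.0313 Da);
    heavy 13CD2-formaldehyde adds 2 x 13C and 4 x 2H (34.0631 Da).
    """
    isotope = Isotope(isotope)
    if isotope is Isotope.light:
        return 2 * _C12 + 4 * _H1
    return 2 * _C13 + 4 * _H2


@dataclass(frozen=True)
class LabelScheme:
    """Nominal modification deltas (Da) of the search configuration."""

    light_delta: float = 28.03
    heavy_delta: float = 34.06
    carbamidomethyl: float = 57.02
    oxidation: float = 15.99
    deamidation: float = 0.98

    def __post_init__(self) -> None:
        if self.heavy_delta <= self.light_delta:
            raise ValueError("heavy_delta must exceed light_delta")


#: Residues allowed to carry each named modification.
_MOD_TARGETS = {
    "carbamidomethyl": {"C"},
    "oxidation": {"M"},
    "deamidation": {"N", "Q"},
}

_EXACT_DELTAS = {
    "carbamidomethyl": _pmass.calculate_mass(formula="C2H3NO"),
    "oxidation": _pmass.calculate_mass(formula="O"),
    "deamidation": _pmass.calculate_mass(formula="O") - _pmass.calculate_mass(formula="NH"),
}


def peptide_mass(
    sequence: str,
    mods: Sequence[Tuple[int, float | str]] = (),
    nterm_label: Optional[Isotope | str] = None,
) -> float:
    """Monoisotopic peptide mass: residue sum + water + modification deltas.

    ``mods`` lists (1-based position, delta) pairs; a delta may be a named
    modification ("carbamidomethyl", "oxidation", "deamidation"), validated
    against its target residues, or a numeric Da shift.  ``nterm_label``
    additionally dimethylates the alpha-amine (and every K, which is blocked
    in the same reaction).
    """
    sequence = validate_sequence(sequence, "peptide sequence")
    total = sum(_pmass.std_aa_mass[aa] for aa in sequence) + _WATER
    for pos, delta in mods:
        if not (1 <= pos <= len(sequence)):
            raise ValueError(f"modification position {pos} outside peptide")
        if isinstance(delta, str):
            name = delta
            if sequence[pos - 1] not in _MOD_TARGETS[name]:
                raise ValueError(
                    f"{name} not applicable to residue "
                    f"{sequence[pos - 1]!r} at position {pos}"
                )
            total += _EXACT_DELTAS[name]
        else:
            total += float(delta)
    if nterm_label is not None:
        n_amines = 1 + sequence.count("K")
        total += n_amines * dimethyl_mass_delta(nterm_label)
    return total


# ---------------------------------------------------------------------------
# Aggregation and ratios

def aggregate_areas(
    observations: Iterable[PeptideObservation],
    design: StudyDesign,
    dedup_key: str = "sequence",
    stage: Optional[Stage] = None,
) -> pd.DataFrame:
    """Sum duplicate rows per channel and relabel channels as CTRL/DA.

    ``dedup_key`` is "sequence" (modifications collapsed; the default,
    mirroring duplicate-peptide removal) or "sequence_mods".  Channel areas
    of duplicate rows are summed; a missing area stays missing unless a
    duplicate supplies one.  Channels are mapped to conditions using the
    replicate's labeling orientation.

    Returns a frame with columns sequence, accession, replicate_id, stage,
    area_ctrl, area_da (NaN = missing).
    """
    if dedup_key not in ("sequence", "sequence_mods"):
        raise ConfigurationError(f"unknown dedup_key {dedup_key!r}")
    rows = []
    for o in observations:
        if stage is not None and o.stage != stage:
            continue
        design.orientation(o.replicate_id)  # raises if absent from design
        key_mods = (o.nterm_mod.value, tuple(o.fixed_mods)) if dedup_key == "sequence_mods" else ()
        rows.append(
            {
                "sequence": o.sequence,
                "accession": o.accession,
                "replicate_id": o.replicate_id,
                "stage": o.stage.value,
                "_mods": key_mods,
                "area_light": np.nan if o.area_light is None else o.area_light,
                "area_heavy": np.nan if o.area_heavy is None else o.area_heavy,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["sequence", "accession", "replicate_id", "stage", "area_ctrl", "area_da"]
        )
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(["sequence", "replicate_id", "stage", "_mods"], sort=True)
        .agg(
            accession=("accession", "first"),
            area_light=("area_light", lambda s: s.sum(min_count=1)),
            area_heavy=("area_heavy", lambda s: s.sum(min_count=1)),
        )
        .reset_index()
    )
    ctrl, da = [], []
    for _, row in grouped.iterrows():
        orient = design.orientation(row["replicate_id"])
        if orient.light_condition is Condition.CTRL:
            ctrl.append(row["area_light"])
            da.append(row["area_heavy"])
        else:
            ctrl.append(row["area_heavy"])
            da.append(row["area_light"])
    grouped["area_ctrl"] = ctrl
    grouped["area_da"] = da
    return grouped[
        ["sequence", "accession", "replicate_id", "stage", "area_ctrl", "area_da"]
    ]


def log2_ratios(aggregated: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    """Per-peptide, per-replicate log2(DA/CTRL) with detection flags.

    Output columns per (sequence, replicate): ``log2_ratio`` (NaN when not
    computable), ``da_detected``, ``ctrl_detected``.  Zero or negative areas
    are treated as missing (a zero XIC means not-detected) with a logged
    warning; one-sided detection is condition-only evidence, not a ratio.
    """
    out = aggregated.copy()

    def _clean(v: float, label: str, row) -> float:
        if pd.isna(v):
            return np.nan
        if v <= 0:
            logger.warning(
                "non-positive %s area %.3g for %s in %s treated as missing",
                label,
                v,
                row["sequence"],
                row["replicate_id"],
            )
            return np.nan
        return v

    ctrl = out.apply(lambda r: _clean(r["area_ctrl"], "CTRL", r), axis=1)
    da = out.apply(lambda r: _clean(r["area_da"], "DA", r), axis=1)
    if len(out) == 0:
        ctrl = pd.Series(dtype=float)
        da = pd.Series(dtype=float)
    out["ctrl_detected"] = ctrl.notna()
    out["da_detected"] = da.notna()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["log2_ratio"] = np.log2(da / ctrl)
    return out


class DifferentialClass(str, Enum):
    over = "over"
    under = "under"
    da_only = "da_only"
    ctrl_only = "ctrl_only"
    not_significant = "not_significant"
    insufficient_data = "insufficient_data"


@dataclass
class DifferentialResult:
    """Per-peptide differential outcome across the replicate design."""

    sequence: str
    accession: str
    per_replicate_log2: Sequence[Optional[float]] = field(default_factory=tuple)
    n_observed: int = 0
    mean_log2: Optional[float] = None
    sem_log2: Optional[float] = None
    p_value: Optional[float] = None
    differential_class: DifferentialClass = DifferentialClass.insufficient_data


def _one_sample_p(ratios: np.ndarray) -> float:
    """Two-tailed one-sample t-test of log2 ratios against 0.

    Degenerate zero-variance input: p = 0 for a nonzero mean (the ratio is
    exactly reproducible), p = 1 for an all-zero vector.
    """
    if len(ratios) < 2:
        return float("nan")
    if np.ptp(ratios) == 0.0:
        return 0.0 if ratios[0] != 0.0 else 1.0
    return float(sps.ttest_1samp(ratios, 0.0).pvalue)


def classify_differential(
    sequence: str,
    accession: str,
    ratio_rows: pd.DataFrame,
    design: StudyDesign,
    config: FilterConfig,
) -> DifferentialResult:
    """Classify one peptide from its per-replicate ratio/detection rows."""
    config.validate_against(design)
    n = design.n_replicates
    required = n - config.max_missing
    by_rep = {r["replicate_id"]: r for _, r in ratio_rows.iterrows()}
    per_rep: List[Optional[float]] = []
    da_excl = ctrl_excl = n_da = n_ctrl = 0
    for rid in design.replicate_ids:
        row = by_rep.get(rid)
        if row is None:
            per_rep.append(None)
            continue
        da_det, ctrl_det = bool(row["da_detected"]), bool(row["ctrl_detected"])
        n_da += da_det
        n_ctrl += ctrl_det
        if da_det and ctrl_det:
            per_rep.append(float(row["log2_ratio"]))
        else:
            per_rep.append(None)
            da_excl += da_det and not ctrl_det
            ctrl_excl += ctrl_det and not da_det
    ratios = np.array([r for r in per_rep if r is not None], dtype=float)
    n_obs = len(ratios)

    result = DifferentialResult(
        sequence=sequence,
        accession=accession,
        per_replicate_log2=tuple(per_rep),
        n_observed=n_obs,
    )
    if n_obs >= required:
        mean = float(ratios.mean())
        sem = float(ratios.std(ddof=1) / math.sqrt(n_obs)) if n_obs > 1 else float("nan")
        p = _one_sample_p(ratios)
        result.mean_log2, result.sem_log2, result.p_value = mean, sem, p
        if abs(mean) >= config.log2_threshold and p < config.p_threshold:
            result.differential_class = (
                DifferentialClass.over if mean > 0 else DifferentialClass.under
            )
        else:
            result.differential_class = DifferentialClass.not_significant
    elif da_excl >= required and n_ctrl == 0:
        result.differential_class = DifferentialClass.da_only
    elif ctrl_excl >= required and n_da == 0:
        result.differential_class = DifferentialClass.ctrl_only
    else:
        result.differential_class = DifferentialClass.insufficient_data
    return result


# ---------------------------------------------------------------------------
# Model / Results

class DifferentialAbundance:
    """Differential N-terminal peptide abundance across a label-swap design.

    Parameters
    ----------
    observations : iterable of PeptideObservation
        Peptide-level evidence (typically POSTsel).
    design : StudyDesign
        Light/heavy orientation of every replicate.
    config : FilterConfig, optional
        Fold-change, p-value and missing-value thresholds.
    dedup_key : str
        "sequence" (default) collapses modification variants before
        aggregation; "sequence_mods" keeps them separate.

    ``fit()`` aggregates duplicate rows, orients channels, computes per-
    replicate log2(DA/CTRL) ratios and classifies every peptide, returning a
    :class:`DifferentialAbundanceResults`.
    """

    def __init__(
        self,
        observations: Sequence[PeptideObservation],
        design: StudyDesign,
        config: Optional[FilterConfig] = None,
        dedup_key: str = "sequence",
        stage: Optional[Stage] = Stage.POSTsel,
    ) -> None:
        self.observations = list(observations)
        self.design = design
        self.config = config or FilterConfig()
        self.config.validate_against(design)
        self.dedup_key = dedup_key
        self.stage = stage

    @classmethod
    def from_tables(cls, peptide_table, design_table, **kwargs) -> "DifferentialAbundance":
        from . import io

        return cls(
            io.read_peptide_table(peptide_table),
            io.read_design_table(design_table),
            **kwargs,
        )

    def fit(self) -> "DifferentialAbundanceResults":
        aggregated = aggregate_areas(
            self.observations, self.design, dedup_key=self.dedup_key, stage=self.stage
        )
        ratios = log2_ratios(aggregated, self.design)
        results = []
        if len(ratios):
            for (sequence, accession), rows in ratios.groupby(
                ["sequence", "accession"], sort=True
            ):
                results.append(
                    classify_differential(sequence, accession, rows, self.design, self.config)
                )
        return DifferentialAbundanceResults(self, ratios, results)


class DifferentialAbundanceResults:
    """Fitted differential-abundance results.

    Attributes
    ----------
    results : list of DifferentialResult
    ratio_table : DataFrame of per-replicate ratios and detection flags
    """

    def __init__(
        self,
        model: DifferentialAbundance,
        ratio_table: pd.DataFrame,
        results: List[DifferentialResult],
    ) -> None:
        self.model = model
        self.ratio_table = ratio_table
        self.results = results

    @property
    def frame(self) -> pd.DataFrame:
        """One row per peptide, mirroring the differential output table."""
        design = self.model.design
        rows = []
        for r in self.results:
            row = {
                "sequence": r.sequence,
                "accession": r.accession,
                "n_observed": r.n_observed,
                "mean_log2": np.nan if r.mean_log2 is None else r.mean_log2,
                "sem_log2": np.nan if r.sem_log2 is None else r.sem_log2,
                "p_value": np.nan if r.p_value is None else r.p_value,
                "class": r.differential_class.value,
            }
            for rid, val in zip(design.replicate_ids, r.per_replicate_log2):
                row[f"log2_{rid}"] = np.nan if val is None else val
            rows.append(row)
        cols = [
            "sequence",
            "accession",
            *[f"log2_{rid}" for rid in design.replicate_ids],
            "n_observed",
            "mean_log2",
            "sem_log2",
            "p_value",
            "class",
        ]
        return pd.DataFrame(rows, columns=cols)

    def class_counts(self) -> Dict[str, int]:
        counts = {c.value: 0 for c in DifferentialClass}
        for r in self.results:
            counts[r.differential_class.value] += 1
        return counts

    def significant(self) -> List[DifferentialResult]:
        keep = {
            DifferentialClass.over,
            DifferentialClass.under,
            DifferentialClass.da_only,
            DifferentialClass.ctrl_only,
        }
        return [r for r in self.results if r.differential_class in keep]

    def summary(self) -> str:
        cfg = self.model.config
        counts = self.class_counts()
        lines = [
            "Differential N-terminal peptide abundance (DA vs CTRL)",
            "=" * 56,
            f"replicates: {self.model.design.n_replicates}   "
            f"max missing: {cfg.max_missing}",
            f"fold-change threshold: {cfg.fold_change_threshold:g} "
            f"(|log2| >= {cfg.log2_threshold:.2f})   p < {cfg.p_threshold:g}",
            f"peptides analysed: {len(self.results)}",
            "-" * 56,
        ]
        for name in [c.value for c in DifferentialClass]:
            lines.append(f"  {name:<20s} {counts[name]:6d}")
        lines.append("-" * 56)
        sig = self.frame[self.frame["class"].isin(["over", "under"])]
        if len(sig):
            lines.append("quantitative hits (mean log2 +/- SEM, p):")
            for _, row in sig.sort_values("mean_log2", ascending=False).iterrows():
                lines.append(
                    f"  {row['sequence']:<30s} {row['accession']:<10s} "
                    f"{row['mean_log2']:+.2f} +/- {row['sem_log2']:.2f}  "
                    f"p={row['p_value']:.2g}  {row['class']}"
                )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
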
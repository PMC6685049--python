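"""Cleavage windows, consensus motifs and protease specificity scoring.

Each processed N-terminus defines a cleavage site P1|P1' where P1' is the
first residue of the observed peptide.  A window covers P10...P1 (the flank
removed or upstream of the cut) and P1'...P10' (the first ten residues of the
peptide); slots beyond the protein bounds are padded and excluded from all
counting.  Information content per slot is log2(20) - H (Shannon entropy in
bits); the consensus shows the modal residue wherever its frequency reaches
``min_freq``, with the cleavage arrow between P1 and P1'.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import AMINO_ACIDS, FormatError, ProteinAnnotation

PAD_CHAR = "-"
CLEAVAGE_MARK = "↓"  # down arrow between P1 and P1'


def slot_names(up: int = 10, down: int = 10) -> List[str]:
    """Slot labels P{up}...P1, P1'...P{down}'."""
    return [f"P{i}" for i in range(up, 0, -1)] + [f"P{i}'" for i in range(1, down + 1)]


@dataclass
class CleavageWindow:
    """Residues around one cleavage site, padded at protein bounds."""

    accession: str
    p1_prime: int
    residues: Tuple[str, ...]
    up: int = 10
    down: int = 10

    def __post_init__(self) -> None:
        if len(self.residues) != self.up + self.down:
            raise ValueError(
                f"window must have {self.up + self.down} slots, got {len(self.residues)}"
            )

    @property
    def slots(self) -> List[str]:
        return slot_names(self.up, self.down)

    def as_dict(self) -> Dict[str, str]:
        return dict(zip(self.slots, self.residues))

    def __str__(self) -> str:
        return (
            "".join(self.residues[: self.up])
            + CLEAVAGE_MARK
            + "".join(self.residues[self.up :])
        )


def extract_window(
    annotation: ProteinAnnotation, p1_prime: int, up: int = 10, down: int = 10
) -> CleavageWindow:
    """Extract the P{up}...P{down}' window around a mapped N-terminus."""
    n = len(annotation.sequence)
    if not (1 <= p1_prime <= n):
        raise ValueError(
            f"{annotation.accession}: p1_prime {p1_prime} outside [1, {n}]"
        )
    residues = []
    for pos in range(p1_prime - up, p1_prime + down):
        residues.append(
            annotation.sequence[pos - 1] if 1 <= pos <= n else PAD_CHAR
        )
    return CleavageWindow(
        accession=annotation.accession,
        p1_prime=p1_prime,
        residues=tuple(residues),
        up=up,
        down=down,
    )


def build_frequency_matrix(
    windows: Sequence[CleavageWindow],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-slot residue counts and column-normalized probabilities.

    Pads are excluded per column; an all-pad column keeps zero counts and NaN
    probabilities.  Rows are the 20 residues (alphabetical), columns the
    slots.  Probabilities are scale-invariant: duplicating the window set
    leaves them unchanged.
    """
    if not windows:
        raise ValueError("at least one window is required")
    up, down = windows[0].up, windows[0].down
    slots = slot_names(up, down)
    counts = pd.DataFrame(
        0, index=list(AMINO_ACIDS), columns=slots, dtype=int
    )
    for w in windows:
        if (w.up, w.down) != (up, down):
            raise ValueError("all windows must share the same shape")
        for slot, res in zip(slots, w.residues):
            if res != PAD_CHAR:
                counts.loc[res, slot] += 1
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / totals.replace(0, np.nan)
    return counts, probs


def information_content(
    probabilities: pd.DataFrame, small_sample_counts: Optional[pd.Series] = None
) -> pd.Series:
    """Bits per slot: IC = log2(20) - H(column).

    The optional small-sample correction subtracts (20-1)/(2 ln2 n) given
    per-column observation counts; it is off by default for determinism.
    """
    max_bits = math.log2(len(AMINO_ACIDS))
    ics = {}
    for slot in probabilities.columns:
        col = probabilities[slot].dropna()
        col = col[col > 0]
        if col.empty:
            ics[slot] = float("nan")
            continue
        h = float(-(col * np.log2(col)).sum())
        ic = max_bits - h
        if small_sample_counts is not None:
            n = small_sample_counts[slot]
            if n > 0:
                ic -= (len(AMINO_ACIDS) - 1) / (2 * math.log(2) * n)
        ics[slot] = max(ic, 0.0)
    return pd.Series(ics)


def consensus(probabilities: pd.DataFrame, min_freq: float = 0.2, up: int = 10) -> str:
    """Consensus string with the cleavage arrow between P1 and P1'.

    Per slot: the most frequent residue if its frequency >= ``min_freq``,
    else '.'; ties broken alphabetically (rows are sorted).
    """
    letters = []
    for slot in probabilities.columns:
        col = probabilities[slot]
        if col.isna().all():
            letters.append(".")
            continue
        best = col.sort_index().idxmax()  # alphabetical tie-break
        letters.append(best if col[best] >= min_freq else ".")
    return "".join(letters[:up]) + CLEAVAGE_MARK + "".join(letters[up:])


# ---------------------------------------------------------------------------
# Protease specificity

@dataclass
class SpecificityProfile:
    """Per-position residue preference weights of one protease.

    ``weights`` is residues (20, alphabetical) x positions (P4...P4' by
    default); every position column sums to 1.
    """

    protease_id: str
    weights: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.weights.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(
                f"{self.protease_id}: position columns must sum to 1, got {sums.to_dict()}"
            )

    @property
    def positions(self) -> List[str]:
        return list(self.weights.columns)


def read_specificity_profiles(path) -> List[SpecificityProfile]:
    """Parse a profile TSV: '# protease_id' header line, then a residue x
    position block with a 'residue' header row."""
    profiles = []
    current_id = None
    header: Optional[List[str]] = None
    rows: Dict[str, List[float]] = {}

    def _flush():
        nonlocal current_id, header, rows
        if current_id is not None:
            weights = pd.DataFrame.from_dict(rows, orient="index", columns=header)
            weights = weights.reindex(sorted(weights.index))
            profiles.append(SpecificityProfile(current_id, weights))
        current_id, header, rows = None, None, {}

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                _flush()
                current_id = line[1:].strip()
            elif line.startswith("residue"):
                header = line.split("\t")[1:]
            else:
                parts = line.split("\t")
                if current_id is None or header is None:
                    raise FormatError(f"{path}: data row before profile header")
                rows[parts[0]] = [float(v) for v in parts[1:]]
    _flush()
    return profiles


def load_packaged_profiles() -> List[SpecificityProfile]:
    """The packaged toy specificity profiles (includes an M13.001-like one)."""
    ref = resources.files("mitotails").joinpath("data/protease_profiles.tsv")
    with resources.as_file(ref) as path:
        return read_specificity_profiles(path)


def score_specificity(
    window: CleavageWindow,
    profile: SpecificityProfile,
    background: Optional[Mapping[str, float]] = None,
    min_prob: float = 1e-4,
) -> Optional[float]:
    """Log-likelihood-ratio score of a window under a protease profile.

    score = sum over profile positions of log2(profile_prob / background),
    skipping padded slots.  Probabilities are floored at ``min_prob`` so a
    residue absent from the profile penalises rather than annihilates the
    score.  Returns None when no profile position overlaps a real residue.
    """
    window_at = window.as_dict()
    bg_uniform = 1.0 / len(AMINO_ACIDS)
    score = 0.0
    n_used = 0
    for pos in profile.positions:
        res = window_at.get(pos)
        if res is None or res == PAD_CHAR:
            continue
        p = max(float(profile.weights.loc[res, pos]), min_prob)
        b = max(float(background[res]) if background else bg_uniform, min_prob)
        score += math.log2(p / b)
        n_used += 1
    return score if n_used else None


def rank_proteases(
    windows: Sequence[CleavageWindow],
    profiles: Sequence[SpecificityProfile],
    background: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Rank proteases by mean specificity score over a window set.

    Descending by mean score, ties broken alphabetically by protease id.
    Columns: protease_id, mean_score, n_windows.
    """
    rows = []
    for profile in profiles:
        scores = [
            s
            for s in (score_specificity(w, profile, background) for w in windows)
            if s is not None
        ]
        rows.append(
            {
                "protease_id": profile.protease_id,
                "mean_score": float(np.mean(scores)) if scores else float("nan"),
                "n_windows": len(scores),
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["mean_score", "protease_id"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return df


def score_table(
    windows: Sequence[CleavageWindow], profiles: Sequence[SpecificityProfile],
    background: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Per-window scores, one row per (window, protease)."""
    rows = []
    for w in windows:
        for p in profiles:
            rows.append(
                {
                    "accession": w.accession,
                    "p1_prime": w.p1_prime,
                    "protease_id": p.protease_id,
                    "score": score_specificity(w, p, background),
                }
            )
    return pd.DataFrame(rows)


def proteome_background(proteins: Iterable[ProteinAnnotation]) -> Dict[str, float]:
    """Residue frequencies across a proteome, as a background model."""
    counts = {aa: 0 for aa in AMINO_ACIDS}
    total = 0
    for prot in proteins:
        for aa in prot.sequence:
            counts[aa] += 1
            total += 1
    if total == 0:
        raise ValueError("empty proteome")
    return {aa: c / total for aa, c in counts.items()}
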
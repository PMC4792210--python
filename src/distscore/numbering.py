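"""Common-numbering anchors from a multiple sequence alignment.

Given an already-built MSA (FASTA or Clustal — this module never aligns), a
per-column conservation profile is computed, the most conserved column inside
each user-supplied helix window becomes the helix's ``*.50`` anchor, and the
remaining window columns are numbered down toward the amino terminus and up
toward the carboxyl terminus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

from .bundle_model import CommonLabel, DataError, helix_letter

logger = logging.getLogger("distscore")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = AMINO_ACIDS + GAP + UNKNOWN


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column residue counts of an alignment.

    ``counts`` is a (n_columns × alphabet) DataFrame; ``top_residue`` /
    ``top_percentage`` give, per column, the most frequent amino acid (gaps and
    X never count as the top residue) and its percentage.  Whether gaps sit in
    the percentage denominator is recorded in ``gaps_in_denominator``.
    """

    counts: pd.DataFrame
    n_sequences: int
    gaps_in_denominator: bool = True

    @property
    def n_columns(self) -> int:
        return len(self.counts)

    @property
    def top_residue(self) -> pd.Series:
        aa = self.counts[list(AMINO_ACIDS)]
        return aa.idxmax(axis=1).where(aa.max(axis=1) > 0, other=None)

    @property
    def top_percentage(self) -> pd.Series:
        aa = self.counts[list(AMINO_ACIDS)]
        if self.gaps_in_denominator:
            denom = float(self.n_sequences)
        else:
            denom = (self.n_sequences - self.counts[GAP]).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * aa.max(axis=1) / denom
        return pct.fillna(0.0)

    def to_table(self) -> pd.DataFrame:
        """Tidy per-column summary (column, top residue, percentage, gap count)."""
        return pd.DataFrame(
            {
                "column": np.arange(self.n_columns),
                "top_residue": self.top_residue.to_numpy(),
                "top_percentage": self.top_percentage.to_numpy(),
                "n_gaps": self.counts[GAP].to_numpy(),
            }
        )


@dataclass(frozen=True)
class AnchorAssignment:
    helix_id: str
    column: int  # 0-based alignment column
    residue: str
    conservation: float  # percent
    window: tuple[int, int]  # inclusive column range searched

    def __post_init__(self):
        a, b = self.window
        if not a <= self.column <= b:
            raise DataError(
                f"anchor column {self.column} outside helix {self.helix_id} "
                f"window {a}..{b}"
            )


def read_msa(path: str | Path, fmt: str | None = None) -> list[str]:
    """Read an aligned FASTA or Clustal file into uppercase sequence strings."""
    path = Path(path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in (".aln", ".clustal", ".clw") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return [str(rec.seq).upper() for rec in aln]


def build_profile(msa: list[str], *, gaps_in_denominator: bool = True) -> ConservationProfile:
    """Exact per-column amino-acid counts of an alignment.

    Characters outside the 20 amino acids and '-' are counted as X.  Raises on
    ragged or empty alignments.
    """
    if not msa:
        raise DataError("empty alignment")
    width = len(msa[0])
    if width == 0:
        raise DataError("zero-length alignment")
    if any(len(s) != width for s in msa):
        raise DataError("ragged alignment: sequences have unequal lengths")
    arr = np.array([list(s.upper()) for s in msa])  # (n_seq, n_col)
    counts = pd.DataFrame(
        0, index=pd.RangeIndex(width, name="column"), columns=list(ALPHABET)
    )
    for ch in np.unique(arr):
        key = ch if ch in ALPHABET else UNKNOWN
        counts[key] += (arr == ch).sum(axis=0)
    profile = ConservationProfile(
        counts=counts, n_sequences=len(msa), gaps_in_denominator=gaps_in_denominator
    )
    assert (counts.sum(axis=1) == len(msa)).all()
    return profile


def assign_anchor(
    profile: ConservationProfile, helix_id: str, helix_window: tuple[int, int]
) -> AnchorAssignment:
    """Pick the most conserved column in a helix window as its *.50 anchor.

    Ties break to the lowest column index, with a warning.  All-gap windows
    raise.
    """
    a, b = helix_window
    if a > b or a < 0 or b >= profile.n_columns:
        raise DataError(f"helix window {a}..{b} invalid for {profile.n_columns} columns")
    pct = profile.top_percentage.iloc[a : b + 1]
    top = profile.top_residue.iloc[a : b + 1]
    if top.isna().all():
        raise DataError(f"helix {helix_id}: window {a}..{b} contains only gaps")
    best = float(pct.max())
    winners = pct.index[pct == best]
    col = int(winners[0])
    if len(winners) > 1:
        logger.warning(
            "helix %s: %d columns tie at %.1f%%; picking lowest column %d",
            helix_id,
            len(winners),
            best,
            col,
        )
    return AnchorAssignment(
        helix_id=helix_letter(helix_id),
        column=col,
        residue=str(top.loc[col]),
        conservation=best,
        window=(a, b),
    )


def number_helix(
    anchor: AnchorAssignment,
    helix_window: tuple[int, int] | None = None,
    anchor_label: CommonLabel | None = None,
) -> dict[int, CommonLabel]:
    """Assign common labels to every column of a helix window.

    The anchor column gets ``h.50``; columns toward the amino terminus count
    down, toward the carboxyl terminus count up.  A window so wide that labels
    would reach ``h.00`` or below raises.  The mapping is a bijection between
    window columns and labels.
    """
    a, b = helix_window if helix_window is not None else anchor.window
    if not a <= anchor.column <= b:
        raise DataError(f"anchor column {anchor.column} outside window {a}..{b}")
    if anchor_label is None:
        anchor_label = CommonLabel(anchor.helix_id, 50)
    if anchor_label.helix_id != helix_letter(anchor.helix_id):
        raise DataError("anchor label helix differs from anchor assignment helix")
    first_minor = anchor_label.minor - (anchor.column - a)
    last_minor = anchor_label.minor + (b - anchor.column)
    if first_minor < 1 or last_minor > 99:
        raise DataError(
            f"helix {anchor.helix_id}: window {a}..{b} too wide for the labelling "
            f"convention (would span .{first_minor:02d}–.{last_minor:02d})"
        )
    return {
        col: CommonLabel(anchor.helix_id, first_minor + (col - a))
        for col in range(a, b + 1)
    }


def anchor_report(anchors: list[AnchorAssignment]) -> pd.DataFrame:
    """Tabular anchor summary (one row per helix) for TSV export."""
    return pd.DataFrame(
        {
            "helix_id": [x.helix_id for x in anchors],
            "anchor_column": [x.column for x in anchors],
            "residue": [x.residue for x in anchors],
            "conservation_pct": [x.conservation for x in anchors],
            "window_start": [x.window[0] for x in anchors],
            "window_end": [x.window[1] for x in anchors],
        }
    )
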
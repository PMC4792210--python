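"""Bundle and common-numbering data model.

A *bundle* is a fixed-length selection of Cα positions from a seven-helix
transmembrane (7TM) protein, one ordered segment per helix.  Positions are
addressed by family-wide *common labels* of the form ``h.pp`` (e.g. ``7.50``),
anchored at the most conserved position of each helix (the ``*.50`` anchor) and
counting down toward the amino terminus and up toward the carboxyl terminus.
For microbial rhodopsins the reference bundle has 7 helices (A–G, numbered 1–7
in labels) totalling 170 residues, giving 170·169/2 = 14,365 unordered Cα–Cα
pairs per chain.

Labels are stored as ``(helix_id, minor)`` integer pairs internally and only
rendered/parsed as text at the boundary, so no floating-point label arithmetic
ever happens.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

logger = logging.getLogger("distscore")

HELIX_LETTERS = "ABCDEFG"
ANCHOR_MINOR = 50
#: Minimum helix length of the MR convention (~6 helical turns).
MIN_HELIX_LENGTH = 22


class DistscoreError(Exception):
    """Base class for all package errors."""


class ConfigError(DistscoreError):
    """Invalid bundle definition, mapping, or run configuration."""


class DataError(DistscoreError):
    """Invalid or inconsistent input data (coordinates, alignments, tables)."""


def helix_number(helix_id: str) -> int:
    """Map a helix letter A–G (or numeral '1'–'7') to its numeral 1–7."""
    h = str(helix_id).strip().upper()
    if h in HELIX_LETTERS:
        return HELIX_LETTERS.index(h) + 1
    if h.isdigit() and 1 <= int(h) <= 7:
        return int(h)
    raise ConfigError(f"unknown helix identifier {helix_id!r} (expected A-G or 1-7)")


def helix_letter(helix_id: str) -> str:
    return HELIX_LETTERS[helix_number(helix_id) - 1]


@dataclass(frozen=True, order=True)
class CommonLabel:
    """A common-numbering position, e.g. ``CommonLabel('G', 50)`` rendered '7.50'."""

    helix_id: str
    minor: int

    def __post_init__(self):
        object.__setattr__(self, "helix_id", helix_letter(self.helix_id))
        if not 1 <= self.minor <= 99:
            raise ConfigError(f"label minor index {self.minor} outside 1..99")

    def render(self) -> str:
        return f"{helix_number(self.helix_id)}.{self.minor:02d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    @classmethod
    def parse(cls, text: str) -> "CommonLabel":
        """Parse 'h.pp' text; exact inverse of :meth:`render`."""
        try:
            major, minor = str(text).strip().split(".")
            return cls(helix_letter(major), int(minor))
        except (ValueError, ConfigError) as exc:
            raise ConfigError(f"cannot parse common label {text!r}") from exc


@dataclass(frozen=True)
class HelixSegment:
    """One helix segment of a bundle definition.

    ``common_start``/``common_end`` are the inclusive minor indices of the
    common-numbering range (e.g. 46..67 for a helix spanning 3.46–3.67); the
    anchor is always minor 50.
    """

    helix_id: str
    common_start: int
    common_end: int
    anchor_minor: int = ANCHOR_MINOR
    anchor_conservation: float | None = None  # percent, optional metadata

    def __post_init__(self):
        object.__setattr__(self, "helix_id", helix_letter(self.helix_id))
        if self.common_end < self.common_start:
            raise ConfigError(
                f"helix {self.helix_id}: common range "
                f"{self.common_start}..{self.common_end} is empty"
            )
        if not self.common_start <= self.anchor_minor <= self.common_end:
            raise ConfigError(
                f"helix {self.helix_id}: anchor .{self.anchor_minor} outside "
                f"common range .{self.common_start}..{self.common_end}"
            )
        if self.anchor_conservation is not None and not (
            0 <= self.anchor_conservation <= 100
        ):
            raise ConfigError(
                f"helix {self.helix_id}: anchor conservation "
                f"{self.anchor_conservation} outside 0..100"
            )
        if self.length < MIN_HELIX_LENGTH:
            warnings.warn(
                f"helix {self.helix_id} has {self.length} residues, below the "
                f"{MIN_HELIX_LENGTH}-residue MR convention",
                stacklevel=2,
            )

    @property
    def length(self) -> int:
        return self.common_end - self.common_start + 1

    @property
    def labels(self) -> tuple[CommonLabel, ...]:
        return tuple(
            CommonLabel(self.helix_id, m)
            for m in range(self.common_start, self.common_end + 1)
        )


@dataclass(frozen=True)
class BundleDefinition:
    """Ordered helix segments defining a fixed-length Cα bundle."""

    family_name: str
    helices: tuple[HelixSegment, ...]

    def __post_init__(self):
        object.__setattr__(self, "helices", tuple(self.helices))
        seen = set()
        for h in self.helices:
            if h.helix_id in seen:
                raise ConfigError(f"duplicate helix {h.helix_id} in bundle definition")
            seen.add(h.helix_id)

    @property
    def total_length(self) -> int:
        return sum(h.length for h in self.helices)

    @property
    def n_pairs(self) -> int:
        n = self.total_length
        return n * (n - 1) // 2

    @property
    def positions(self) -> tuple[CommonLabel, ...]:
        """All bundle positions in canonical order (helix order, N→C per helix)."""
        out: list[CommonLabel] = []
        for h in self.helices:
            out.extend(h.labels)
        return tuple(out)

    def helix(self, helix_id: str) -> HelixSegment:
        hid = helix_letter(helix_id)
        for h in self.helices:
            if h.helix_id == hid:
                return h
        raise ConfigError(f"bundle has no helix {helix_id!r}")

    def index_of(self, label: CommonLabel) -> int:
        try:
            return self.positions.index(label)
        except ValueError:
            raise ConfigError(f"label {label.render()} not in bundle") from None


@dataclass(frozen=True)
class ResidueMapping:
    """Author-numbering ranges of one structure chain onto a bundle definition.

    ``author_ranges`` maps helix_id → inclusive (start, end) author residue
    numbers; ``declared_missing`` lists common labels this chain is known to
    lack (the author range is correspondingly shorter and labels are skipped
    in order).
    """

    structure_id: str
    chain_id: str
    author_ranges: Mapping[str, tuple[int, int]]
    declared_missing: tuple[CommonLabel, ...] = ()

    def __post_init__(self):
        ranges = {helix_letter(k): (int(v[0]), int(v[1])) for k, v in self.author_ranges.items()}
        object.__setattr__(self, "author_ranges", ranges)
        object.__setattr__(self, "declared_missing", tuple(self.declared_missing))
        for hid, (a, b) in ranges.items():
            if b < a:
                raise ConfigError(
                    f"{self.structure_id}/{self.chain_id} helix {hid}: "
                    f"author range {a}..{b} is decreasing"
                )

    def validate(self, bundle: BundleDefinition) -> None:
        """Check range lengths against the bundle (helix length − declared missing)."""
        missing_by_helix: dict[str, int] = {}
        for lab in self.declared_missing:
            missing_by_helix[lab.helix_id] = missing_by_helix.get(lab.helix_id, 0) + 1
        for h in bundle.helices:
            if h.helix_id not in self.author_ranges:
                raise ConfigError(
                    f"{self.structure_id}/{self.chain_id}: no author range for "
                    f"helix {h.helix_id}"
                )
            a, b = self.author_ranges[h.helix_id]
            expected = h.length - missing_by_helix.get(h.helix_id, 0)
            if b - a + 1 != expected:
                raise ConfigError(
                    f"{self.structure_id}/{self.chain_id} helix {h.helix_id}: author "
                    f"range {a}..{b} has {b - a + 1} residues, expected {expected} "
                    f"({h.length} minus {missing_by_helix.get(h.helix_id, 0)} declared missing)"
                )
        for lab in self.declared_missing:
            bundle.index_of(lab)  # raises if the label is not a bundle position

    def author_to_label(self, bundle: BundleDefinition) -> dict[int, CommonLabel]:
        """Map every mapped author residue to its common label."""
        self.validate(bundle)
        missing = set(self.declared_missing)
        out: dict[int, CommonLabel] = {}
        for h in bundle.helices:
            a, b = self.author_ranges[h.helix_id]
            present_labels = [lab for lab in h.labels if lab not in missing]
            for res, lab in zip(range(a, b + 1), present_labels):
                out[res] = lab
        return out


# ---------------------------------------------------------------------------
# Common numbering
# ---------------------------------------------------------------------------

def common_number(
    author_residue: int,
    helix_author_range: tuple[int, int],
    helix: HelixSegment,
) -> CommonLabel:
    """Common label of an author residue given the helix's author range.

    The helix's first mapped residue takes the first common label and numbering
    ascends toward the carboxy terminus, so the ``*.50`` anchor falls on the
    residue ``50 − common_start`` positions into the range.
    """
    a, b = helix_author_range
    if not a <= author_residue <= b:
        raise DataError(
            f"residue {author_residue} outside helix {helix.helix_id} "
            f"author range {a}..{b}"
        )
    if b - a + 1 != helix.length:
        raise ConfigError(
            f"author range {a}..{b} length {b - a + 1} does not match helix "
            f"{helix.helix_id} length {helix.length}"
        )
    return CommonLabel(helix.helix_id, helix.common_start + (author_residue - a))


def author_residue_of(
    label: CommonLabel, helix_author_range: tuple[int, int], helix: HelixSegment
) -> int:
    """Inverse of :func:`common_number`."""
    if label.helix_id != helix.helix_id:
        raise DataError(f"label {label.render()} is not on helix {helix.helix_id}")
    if not helix.common_start <= label.minor <= helix.common_end:
        raise DataError(
            f"label {label.render()} outside helix {helix.helix_id} common range"
        )
    return helix_author_range[0] + (label.minor - helix.common_start)


# ---------------------------------------------------------------------------
# Pair enumeration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairIndex:
    """All unordered residue pairs of a bundle in canonical condensed order.

    Canonical order is row-major over bundle positions 0..N−1 (helix order
    A→G), pair (i, j) with i < j — identical to the condensed order used by
    :func:`scipy.spatial.distance.pdist`, so distance vectors line up with
    this index with no reshuffling.
    """

    bundle: BundleDefinition
    i: np.ndarray = field(repr=False)  # (P,) int
    j: np.ndarray = field(repr=False)  # (P,) int
    kind: np.ndarray = field(repr=False)  # (P,) 'intra' | 'inter'
    group: np.ndarray = field(repr=False)  # (P,) helix id or 'X-Y' helix pair

    def __len__(self) -> int:
        return len(self.i)

    @property
    def labels(self) -> tuple[CommonLabel, ...]:
        return self.bundle.positions

    def label_pairs(self) -> list[tuple[CommonLabel, CommonLabel]]:
        pos = self.bundle.positions
        return [(pos[a], pos[b]) for a, b in zip(self.i, self.j)]

    def counts(self) -> dict[str, int]:
        """Total, intrahelical and interhelical pair counts."""
        intra = int(np.sum(self.kind == "intra"))
        return {"total": len(self), "intra": intra, "inter": len(self) - intra}


def enumerate_pairs(bundle: BundleDefinition) -> PairIndex:
    """Enumerate all N·(N−1)/2 residue pairs with intra/interhelical classes."""
    n = bundle.total_length
    helix_of = np.concatenate(
        [np.full(h.length, k) for k, h in enumerate(bundle.helices)]
    )
    iu, ju = np.triu_indices(n, k=1)
    hi, hj = helix_of[iu], helix_of[ju]
    letters = np.array([h.helix_id for h in bundle.helices])
    kind = np.where(hi == hj, "intra", "inter")
    group = np.where(
        hi == hj,
        letters[hi],
        np.char.add(np.char.add(letters[hi], "-"), letters[hj]),
    )
    return PairIndex(bundle=bundle, i=iu, j=ju, kind=kind, group=group)


# ---------------------------------------------------------------------------
# Plain-text configuration I/O
# ---------------------------------------------------------------------------

BUNDLE_COLUMNS = ["helix_id", "common_start", "common_end", "anchor_label"]
MAPPING_COLUMNS = [
    "structure_id",
    "chain_id",
    "helix_id",
    "author_start",
    "author_end",
    "missing_labels",
]


def _read_tsv_rows(path: Path) -> tuple[list[str], list[list[str]]]:
    lines = Path(path).read_text().splitlines()
    rows = [ln.split("\t") for ln in lines if ln.strip() and not ln.startswith("#")]
    if not rows:
        raise ConfigError(f"{path}: no data rows")
    header = [c.strip() for c in rows[0]]
    return header, rows[1:]


def _family_from_comments(path: Path) -> str | None:
    for ln in Path(path).read_text().splitlines():
        if ln.startswith("#") and "family" in ln and "=" in ln:
            return ln.split("=", 1)[1].strip()
    return None


def load_bundle_definition(path: str | Path, family_name: str | None = None) -> BundleDefinition:
    """Load a bundle definition from a TSV file (one row per helix)."""
    path = Path(path)
    header, rows = _read_tsv_rows(path)
    missing = [c for c in BUNDLE_COLUMNS if c not in header]
    if missing:
        raise ConfigError(f"{path}: missing columns {missing}; found {header}")
    col = {c: header.index(c) for c in header}
    helices = []
    for row in rows:
        start = CommonLabel.parse(row[col["common_start"]])
        end = CommonLabel.parse(row[col["common_end"]])
        anchor = CommonLabel.parse(row[col["anchor_label"]])
        hid = helix_letter(row[col["helix_id"]])
        if not start.helix_id == end.helix_id == anchor.helix_id == hid:
            raise ConfigError(
                f"{path}: helix {hid} row mixes labels from different helices"
            )
        cons = None
        if "anchor_conservation" in col and len(row) > col["anchor_conservation"]:
            text = row[col["anchor_conservation"]].strip()
            cons = float(text) if text else None
        helices.append(
            HelixSegment(hid, start.minor, end.minor, anchor.minor, cons)
        )
    family = family_name or _family_from_comments(path) or path.stem
    return BundleDefinition(family_name=family, helices=tuple(helices))


def load_mappings(path: str | Path) -> list[ResidueMapping]:
    """Load residue mappings from a TSV file (one row per chain per helix)."""
    path = Path(path)
    header, rows = _read_tsv_rows(path)
    required = MAPPING_COLUMNS[:-1]  # missing_labels may be absent entirely
    absent = [c for c in required if c not in header]
    if absent:
        raise ConfigError(f"{path}: missing columns {absent}; found {header}")
    col = {c: header.index(c) for c in header}
    grouped: dict[tuple[str, str], dict] = {}
    for row in rows:
        key = (row[col["structure_id"]].strip(), row[col["chain_id"]].strip())
        entry = grouped.setdefault(key, {"ranges": {}, "missing": []})
        hid = helix_letter(row[col["helix_id"]])
        if hid in entry["ranges"]:
            raise ConfigError(f"{path}: duplicate helix {hid} for {key}")
        entry["ranges"][hid] = (
            int(row[col["author_start"]]),
            int(row[col["author_end"]]),
        )
        if "missing_labels" in col and len(row) > col["missing_labels"]:
            text = row[col["missing_labels"]].strip()
            if text:
                entry["missing"].extend(
                    CommonLabel.parse(t) for t in text.split(",") if t.strip()
                )
    return [
        ResidueMapping(
            structure_id=sid,
            chain_id=cid,
            author_ranges=e["ranges"],
            declared_missing=tuple(dict.fromkeys(e["missing"])),
        )
        for (sid, cid), e in grouped.items()
    ]


def mr_reference_bundle() -> BundleDefinition:
    """The packaged 170-residue microbial-rhodopsin reference bundle."""
    with resources.as_file(
        resources.files("distscore.data").joinpath("mr_bundle.tsv")
    ) as p:
        return load_bundle_definition(p)


def br_reference_mapping() -> ResidueMapping:
    """The packaged bacteriorhodopsin author-numbering mapping (e.g. 1PY6)."""
    with resources.as_file(
        resources.files("distscore.data").joinpath("br_mapping.tsv")
    ) as p:
        (mapping,) = load_mappings(p)
    return mapping
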
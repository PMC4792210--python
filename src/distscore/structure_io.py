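"""Coordinate I/O: Cα extraction from PDB/mmCIF and tabular result files.

Coordinate files are parsed with gemmi; residues are addressed by author
numbering (``auth_seq_id``), matching the serials used in the literature for
bacteriorhodopsin (e.g. Lys216).  Insertion codes are rejected.  Alternate
locations are resolved to the highest-occupancy Cα, ties broken by altloc
identifier order.  All coordinates are in Å throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .bundle_model import BundleDefinition, ConfigError, DataError, ResidueMapping

logger = logging.getLogger("distscore")


@dataclass
class ChainBundle:
    """One chain's Cα coordinates laid out over a bundle definition.

    ``coords`` has one (x, y, z) row per bundle position in canonical order;
    rows where ``present`` is False hold NaN.
    """

    structure_id: str
    chain_id: str
    coords: np.ndarray  # (N, 3) float64, NaN where absent
    present: np.ndarray  # (N,) bool
    bundle: BundleDefinition = field(repr=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        n = self.bundle.total_length
        if self.coords.shape != (n, 3):
            raise DataError(
                f"{self.structure_id}/{self.chain_id}: coords shape "
                f"{self.coords.shape} != ({n}, 3)"
            )
        if self.present.shape != (n,):
            raise DataError("presence mask length mismatch")
        if not np.all(np.isfinite(self.coords[self.present])):
            raise DataError(
                f"{self.structure_id}/{self.chain_id}: non-finite coordinates "
                "at present positions"
            )
        self.coords = self.coords.copy()
        self.coords[~self.present] = np.nan

    @property
    def n_present(self) -> int:
        return int(self.present.sum())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ChainBundle":
        """A rigid-body moved copy (coords → R·x + t)."""
        new = np.full_like(self.coords, np.nan)
        new[self.present] = self.coords[self.present] @ np.asarray(rotation).T + translation
        return ChainBundle(
            self.structure_id, self.chain_id, new, self.present.copy(), self.bundle
        )


# ---------------------------------------------------------------------------
# Reading coordinates
# ---------------------------------------------------------------------------

def read_ca_coordinates(structure_file: str | Path, chain_id: str) -> dict[int, np.ndarray]:
    """Read one Cα position per author residue number for a chain.

    Returns a map ``author_seq_id → (3,) array``.  Residues without a Cα are
    omitted; alternate-location Cαs resolve to the highest occupancy, ties to
    the lowest altloc identifier.
    """
    path = Path(structure_file)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise DataError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise DataError(f"{path}: structure has no models")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = sorted({ch.name for ch in model})
        raise DataError(
            f"{path}: chain {chain_id!r} not found; available chains: {available}"
        )
    out: dict[int, np.ndarray] = {}
    for residue in chain:
        if residue.seqid.icode not in (" ", "", "\x00"):
            raise DataError(
                f"{path} chain {chain_id}: insertion code "
                f"{residue.seqid.icode!r} at residue {residue.seqid.num} unsupported"
            )
        cas = [a for a in residue if a.name == "CA" and a.element.name != "Ca"]
        if not cas:
            continue
        # highest occupancy wins; ties broken by altloc identifier order
        best = min(cas, key=lambda a: (-a.occ, a.altloc or "A"))
        num = residue.seqid.num
        if num in out:
            # same author number repeated (e.g. microheterogeneity); keep first
            continue
        out[num] = np.array([best.pos.x, best.pos.y, best.pos.z], dtype=float)
    return out


def extract_bundle(
    ca_map: dict[int, np.ndarray],
    mapping: ResidueMapping,
    bundle: BundleDefinition,
) -> ChainBundle:
    """Fill bundle positions from a Cα map according to a residue mapping.

    Declared-missing labels and residues absent from the file are masked (the
    latter with a warning); a mapped author range lying outside the chain's
    observed residue span is treated as a mapping bug and raises.
    """
    mapping.validate(bundle)
    if not ca_map:
        raise DataError(f"{mapping.structure_id}/{mapping.chain_id}: empty Cα map")
    lo, hi = min(ca_map), max(ca_map)
    n = bundle.total_length
    coords = np.full((n, 3), np.nan)
    present = np.zeros(n, dtype=bool)
    missing = set(mapping.declared_missing)
    pos = 0
    for h in bundle.helices:
        a, b = mapping.author_ranges[h.helix_id]
        if a < lo or b > hi:
            raise ConfigError(
                f"{mapping.structure_id}/{mapping.chain_id} helix {h.helix_id}: "
                f"author range {a}..{b} extends beyond the chain's residues "
                f"({lo}..{hi}); check the mapping"
            )
        res_iter = iter(range(a, b + 1))
        for lab in h.labels:
            if lab in missing:
                pos += 1
                continue
            res = next(res_iter)
            xyz = ca_map.get(res)
            if xyz is None:
                logger.warning(
                    "%s/%s: residue %d (%s) has no Cα in the file; masked",
                    mapping.structure_id,
                    mapping.chain_id,
                    res,
                    lab.render(),
                )
            else:
                coords[pos] = xyz
                present[pos] = True
            pos += 1
    return ChainBundle(mapping.structure_id, mapping.chain_id, coords, present, bundle)


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

PAIR_TABLE_COLUMNS = [
    "pair_index",
    "label_i",
    "label_j",
    "kind",
    "group",
    "n_chains",
    "mean",
    "std",
    "score",
]


def write_pair_table(stats: pd.DataFrame, out: str | Path) -> None:
    """Write per-pair statistics as TSV (one row per pair, header included)."""
    if stats is None or len(stats) == 0:
        raise DataError("refusing to write an empty pair table")
    missing = [c for c in PAIR_TABLE_COLUMNS if c not in stats.columns]
    if missing:
        raise DataError(f"pair table missing columns {missing}")
    stats.to_csv(out, sep="\t", index=False, columns=PAIR_TABLE_COLUMNS)


def read_pair_table(path: str | Path) -> pd.DataFrame:
    """Companion reader for :func:`write_pair_table`; round-trips bit-exactly
    within text float precision."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"label_i": str, "label_j": str, "kind": str, "group": str},
    )
    missing = [c for c in PAIR_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: not a pair table, missing columns {missing}")
    return df


def write_matrix(matrix: pd.DataFrame, out: str | Path) -> None:
    """Write a labelled symmetric chain-by-chain matrix as TSV."""
    matrix.to_csv(out, sep="\t", index=True, index_label="chain")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="chain")
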
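"""Synthetic 7TM Cα bundles, ensembles and alignments.

Generates idealized helical Cα traces placed on a circle with alternating
up/down orientation, perturbed ensembles (per-residue Gaussian noise with a
per-helix scale, plus one rigid-body motion per chain), and synthetic MSAs
with planted per-column conservation levels.  Everything is driven by an
explicit seed through a single :class:`numpy.random.Generator` per call, so
the same spec and seed give bit-identical output.

The geometry defaults follow a regular α-helix: 1.5 Å rise and 100° twist per
residue on a 2.3 Å helix radius (consecutive Cα–Cα chord ≈ 3.8 Å), helices on
an 11 Å placement circle.  This is a test double for real 7TM bundles: it is
topologically faithful (seven roughly parallel, alternating helices; realistic
intra- and interhelical distance scales) but makes no claim to native
rhodopsin geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .bundle_model import (
    BundleDefinition,
    CommonLabel,
    ConfigError,
    HelixSegment,
    HELIX_LETTERS,
)
from .structure_io import ChainBundle

DEFAULT_HELIX_LENGTHS = (22, 24, 22, 24, 28, 25, 25)  # MR reference bundle


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic bundle generator.

    noise_sigma is the isotropic per-residue Gaussian displacement (Å), either
    one scalar for all helices or a per-helix map; jitter_* bound the random
    rigid-body motion applied once per chain.
    """

    helix_lengths: tuple[int, ...] = DEFAULT_HELIX_LENGTHS
    rise_per_residue: float = 1.5  # Å
    turn_per_residue: float = 100.0  # degrees
    helix_radius: float = 2.3  # Å
    placement_radius: float = 11.0  # Å
    noise_sigma: float | Mapping[str, float] = 0.3  # Å
    jitter_max_rotation: float = 10.0  # degrees
    jitter_max_translation: float = 5.0  # Å
    n_chains: int = 10
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "helix_lengths", tuple(int(x) for x in self.helix_lengths))
        if not 1 <= len(self.helix_lengths) <= 7:
            raise ConfigError("helix_lengths: need 1..7 helices")
        if any(n < 2 for n in self.helix_lengths):
            raise ConfigError("helix_lengths: every helix needs ≥ 2 residues")
        for name in ("rise_per_residue", "helix_radius", "placement_radius"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("jitter_max_rotation", "jitter_max_translation"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be ≥ 0")
        if isinstance(self.noise_sigma, Mapping):
            bad = [k for k, v in self.noise_sigma.items() if v < 0]
        else:
            bad = [] if self.noise_sigma >= 0 else ["noise_sigma"]
        if bad:
            raise ConfigError(f"noise_sigma must be ≥ 0 (offending: {bad})")
        if self.n_chains < 1:
            raise ConfigError("n_chains must be ≥ 1")

    @property
    def helix_ids(self) -> tuple[str, ...]:
        return tuple(HELIX_LETTERS[: len(self.helix_lengths)])

    def sigma_of(self, helix_id: str) -> float:
        if isinstance(self.noise_sigma, Mapping):
            return float(self.noise_sigma.get(helix_id, 0.0))
        return float(self.noise_sigma)

    def bundle_definition(self) -> BundleDefinition:
        """A bundle definition matching the generated geometry, anchors at .50."""
        helices = []
        for hid, length in zip(self.helix_ids, self.helix_lengths):
            start = 50 - (length // 2)
            helices.append(HelixSegment(hid, start, start + length - 1))
        return BundleDefinition(family_name="synthetic", helices=tuple(helices))


def ideal_consecutive_ca_distance(spec: SyntheticSpec) -> float:
    """Closed-form chord length between consecutive Cαs of the ideal helix."""
    half_turn = np.deg2rad(spec.turn_per_residue) / 2.0
    chord = 2.0 * spec.helix_radius * np.sin(half_turn)
    return float(np.hypot(spec.rise_per_residue, chord))


def make_ideal_bundle(spec: SyntheticSpec) -> ChainBundle:
    """Idealized Cα bundle: helical traces on a circle, alternating up/down."""
    bundle = spec.bundle_definition()
    k_helices = len(spec.helix_lengths)
    coords = []
    for k, length in enumerate(spec.helix_lengths):
        t = np.arange(length)
        theta = np.deg2rad(spec.turn_per_residue) * t
        local = np.column_stack(
            [
                spec.helix_radius * np.cos(theta),
                spec.helix_radius * np.sin(theta),
                spec.rise_per_residue * (t - (length - 1) / 2.0),
            ]
        )
        if k % 2 == 1:  # every other helix runs N→C downward
            local[:, 2] *= -1.0
            local[:, 1] *= -1.0  # keep handedness of the trace
        phi = 2.0 * np.pi * k / k_helices
        center = spec.placement_radius * np.array([np.cos(phi), np.sin(phi), 0.0])
        coords.append(local + center)
    xyz = np.vstack(coords)
    return ChainBundle(
        structure_id="ideal",
        chain_id="A",
        coords=xyz,
        present=np.ones(len(xyz), dtype=bool),
        bundle=bundle,
    )


def _random_rigid_motion(rng: np.random.Generator, max_rot_deg: float, max_trans: float):
    axis = rng.normal(size=3)
    norm = np.linalg.norm(axis)
    axis = axis / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
    angle = np.deg2rad(rng.uniform(0.0, max_rot_deg))
    rot = Rotation.from_rotvec(angle * axis).as_matrix()
    trans = rng.uniform(-max_trans, max_trans, size=3)
    return rot, trans


def make_ensemble(
    spec: SyntheticSpec,
    *,
    per_helix_sigma: Mapping[str, float] | None = None,
    n_chains: int | None = None,
    seed: int | None = None,
    declared_missing: Sequence[CommonLabel] = (),
) -> list[ChainBundle]:
    """Perturbed ensemble: ideal bundle + per-residue noise + per-chain rigid motion.

    Keyword overrides take precedence over the spec's own fields.  Labels in
    ``declared_missing`` are masked in every chain, exercising the
    partial-presence code paths downstream.
    """
    if per_helix_sigma is not None or n_chains is not None or seed is not None:
        spec = replace(
            spec,
            noise_sigma=dict(per_helix_sigma) if per_helix_sigma is not None else spec.noise_sigma,
            n_chains=n_chains if n_chains is not None else spec.n_chains,
            seed=seed if seed is not None else spec.seed,
        )
    if spec.n_chains < 2:
        raise ConfigError("an ensemble needs n_chains ≥ 2")
    ideal = make_ideal_bundle(spec)
    bundle = ideal.bundle
    sigma_per_pos = np.concatenate(
        [
            np.full(length, spec.sigma_of(hid))
            for hid, length in zip(spec.helix_ids, spec.helix_lengths)
        ]
    )
    mask = np.ones(bundle.total_length, dtype=bool)
    for lab in declared_missing:
        mask[bundle.index_of(lab)] = False
    rng = np.random.default_rng(spec.seed)
    chains = []
    for k in range(spec.n_chains):
        noise = rng.normal(size=(bundle.total_length, 3)) * sigma_per_pos[:, None]
        rot, trans = _random_rigid_motion(
            rng, spec.jitter_max_rotation, spec.jitter_max_translation
        )
        xyz = (ideal.coords + noise) @ rot.T + trans
        chains.append(
            ChainBundle(
                structure_id=f"synth{k:02d}",
                chain_id="A",
                coords=xyz,
                present=mask.copy(),
                bundle=bundle,
            )
        )
    return chains


def make_synthetic_msa(
    n_sequences: int,
    conservation_levels: Sequence[float],
    seed: int,
    top_residues: Sequence[str] | None = None,
) -> list[str]:
    """Aligned sequences with a planted top-residue fraction per column.

    Column c's designated top residue appears with probability
    ``conservation_levels[c]``; otherwise a uniformly random different amino
    acid is drawn.
    """
    from .numbering import AMINO_ACIDS

    levels = np.asarray(conservation_levels, dtype=float)
    if np.any((levels < 0) | (levels > 1)):
        raise ConfigError("conservation levels must lie in [0, 1]")
    if n_sequences < 1:
        raise ConfigError("need ≥ 1 sequence")
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    if top_residues is None:
        tops = aas[np.arange(len(levels)) % len(aas)]
    else:
        tops = np.array([t.upper() for t in top_residues])
        if len(tops) != len(levels):
            raise ConfigError("top_residues length must match conservation levels")
    cols = []
    for p, top in zip(levels, tops):
        others = aas[aas != top]
        hit = rng.random(n_sequences) < p
        col = np.where(hit, top, others[rng.integers(0, len(others), size=n_sequences)])
        cols.append(col)
    arr = np.column_stack(cols)
    return ["".join(row) for row in arr]


# ---------------------------------------------------------------------------
# Writing synthetic ensembles to disk (exercises the full I/O path)
# ---------------------------------------------------------------------------

LOOP_GAP = 5  # author-numbering residues left between consecutive helices


def author_ranges_for(spec: SyntheticSpec, start: int = 11) -> dict[str, tuple[int, int]]:
    """Contiguous author ranges per helix with short loop gaps in between."""
    ranges = {}
    pos = start
    for hid, length in zip(spec.helix_ids, spec.helix_lengths):
        ranges[hid] = (pos, pos + length - 1)
        pos += length + LOOP_GAP
    return ranges


def write_chain_pdb(chain: ChainBundle, author_numbers: Sequence[int], path: str | Path) -> None:
    """Write one chain as a minimal poly-ALA Cα PDB file."""
    st = gemmi.Structure()
    st.name = chain.structure_id
    model = gemmi.Model("1")
    gch = gemmi.Chain(chain.chain_id)
    serial = 1
    for num, xyz, ok in zip(author_numbers, chain.coords, chain.present):
        if not ok:
            continue
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(int(num), " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*map(float, xyz))
        atom.occ = 1.0
        atom.serial = serial
        serial += 1
        res.add_atom(atom)
        gch.add_residue(res)
    model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_ensemble(
    ensemble: list[ChainBundle],
    spec: SyntheticSpec,
    out_dir: str | Path,
) -> tuple[Path, Path, list[Path]]:
    """Write PDB files plus matching bundle-definition and mapping TSVs.

    Returns (bundle_def_path, mappings_path, pdb_paths).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = spec.bundle_definition()
    ranges = author_ranges_for(spec)

    bundle_path = out / "bundle.tsv"
    rows = ["helix_id\tcommon_start\tcommon_end\tanchor_label"]
    for h in bundle.helices:
        rows.append(
            f"{h.helix_id}\t{CommonLabel(h.helix_id, h.common_start).render()}"
            f"\t{CommonLabel(h.helix_id, h.common_end).render()}"
            f"\t{CommonLabel(h.helix_id, h.anchor_minor).render()}"
        )
    bundle_path.write_text("\n".join(rows) + "\n")

    map_path = out / "mappings.tsv"
    rows = ["structure_id\tchain_id\thelix_id\tauthor_start\tauthor_end\tmissing_labels"]
    pdb_paths = []
    for chain in ensemble:
        # declared missing per helix: masked labels, author range shrinks accordingly
        masked = [bundle.positions[k] for k in np.flatnonzero(~chain.present)]
        missing_by_helix: dict[str, list[str]] = {h.helix_id: [] for h in bundle.helices}
        for lab in masked:
            missing_by_helix[lab.helix_id].append(lab.render())
        for hid in spec.helix_ids:
            a, b = ranges[hid]
            b_eff = b - len(missing_by_helix[hid])
            rows.append(
                f"{chain.structure_id}\t{chain.chain_id}\t{hid}\t{a}\t{b_eff}\t"
                + ",".join(missing_by_helix[hid])
            )
        # compact author numbering: present residues numbered consecutively per helix
        nums = []
        start = 0
        for hid, length in zip(spec.helix_ids, spec.helix_lengths):
            a, _ = ranges[hid]
            n = 0
            for k in range(start, start + length):
                if chain.present[k]:
                    nums.append(a + n)
                    n += 1
                else:
                    nums.append(-1)  # unused: masked slot
            start += length
        pdb = out / f"{chain.structure_id}.pdb"
        write_chain_pdb(chain, nums, pdb)
        pdb_paths.append(pdb)
    map_path.write_text("\n".join(rows) + "\n")
    return bundle_path, map_path, pdb_paths
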
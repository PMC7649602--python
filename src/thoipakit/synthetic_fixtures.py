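"""Seeded generators for fully synthetic test data.

Every generator is a pure function of its spec (including the seed): repeated
calls with the same arguments are identical.  The generators emulate

* homologue MSAs with planted conserved columns, planted pairwise couplings
  and locally correlated "segment" mutations (the latter reproduce the high
  background coevolution between sequence neighbours seen in real MSAs);
* ideal two-chain alpha-helix dimers (1.5 A rise, 100 deg/residue twist,
  side chains as a single C-beta pseudo-atom 2.4 A from the C-alpha) with a
  geometrically known facing-residue mask;
* scanning-mutagenesis tables with a planted interface and configurable
  effect size and noise;
* a labelled multi-TMD benchmark carrying the qualitative signal structure
  of real homotypic interfaces (GxxxG pairs, elevated conservation and
  polarity, alpha-helical periodicity, central depth bias).

It also provides a synthetic stand-in for the per-residue interface
annotations of the packaged 50-TMD reference set (see
:func:`synthetic_reference_masks`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import yaml

from . import errors
from .datasets import MutagenesisRecord, TMDRecord
from .msa_features import Alignment, depth_profile
from .reference import AMINO_ACIDS, load_reference_table

HELIX_RISE = 1.5  # A per residue
HELIX_TWIST = 100.0  # degrees per residue
CA_RADIUS = 2.3  # A, C-alpha distance from the helix axis
CB_LENGTH = 2.4  # A, pseudo side-chain atom beyond the C-alpha
CB_RADIUS = CA_RADIUS + CB_LENGTH


@dataclass
class FixtureSpec:
    """Specification of a synthetic MSA / mutagenesis fixture."""

    L: int = 21
    n_seqs: int = 100
    conserved_positions: tuple = ()  # 0-based column indices
    coupled_pairs: tuple = ()  # (p, q, strength) with 0 <= strength <= 1
    interface_positions: tuple = ()  # 0-based, for mutagenesis fixtures
    effect_size: float = 0.5
    noise: float = 0.0
    seed: int = 0
    segment_rate: float = field(default=2.0)  # mean correlated-mutation events per row
    background_flip: float = 0.4  # per-column substitution probability
    conserved_flip: float = 0.05

    def __post_init__(self):
        for p in self.conserved_positions:
            if not 0 <= p < self.L:
                raise errors.SpecError(f"conserved position {p} outside 0..{self.L - 1}")
        coupled_cols = set()
        for p, q, s in self.coupled_pairs:
            if not (0 <= p < self.L and 0 <= q < self.L) or p == q:
                raise errors.SpecError(f"bad coupled pair ({p}, {q})")
            if not 0 <= s <= 1:
                raise errors.SpecError(f"coupling strength {s} outside [0, 1]")
            coupled_cols.update((p, q))
        if coupled_cols & set(self.conserved_positions):
            raise errors.SpecError("conserved and coupled positions overlap")
        for p in self.interface_positions:
            if not 0 <= p < self.L:
                raise errors.SpecError(f"interface position {p} outside 0..{self.L - 1}")

    def to_yaml(self, path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        data["coupled_pairs"] = [list(t) for t in self.coupled_pairs]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "FixtureSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("conserved_positions", "interface_positions"):
            data[key] = tuple(data.get(key, ()))
        data["coupled_pairs"] = tuple(tuple(t) for t in data.get("coupled_pairs", ()))
        return cls(**data)


@lru_cache(maxsize=1)
def membrane_background_composition() -> tuple:
    """Mean amino-acid composition of the packaged reference TMD sequences.

    Returned as (letters, probabilities); computed from the shipped sequence
    table rather than hard-coded.
    """
    counts = dict.fromkeys(AMINO_ACIDS, 0)
    for seq in load_reference_table().sequence:
        for ch in seq:
            counts[ch] += 1
    total = sum(counts.values())
    letters = tuple(AMINO_ACIDS)
    probs = tuple(counts[a] / total for a in letters)
    return letters, probs


def _draw_background(rng, size):
    letters, probs = membrane_background_composition()
    return rng.choice(list(letters), size=size, p=probs)


# ---------------------------------------------------------------------------
# MSA generator
# ---------------------------------------------------------------------------

def synth_msa(spec: FixtureSpec) -> Alignment:
    """Synthetic homologue alignment with planted conservation and couplings."""
    if spec.n_seqs < 2:
        raise errors.SpecError("n_seqs must be >= 2")
    rng = np.random.default_rng(spec.seed)
    consensus = _draw_background(rng, spec.L)
    conserved = np.zeros(spec.L, dtype=bool)
    conserved[list(spec.conserved_positions)] = True
    # two-state letters for each coupled column
    pair_states = []
    for p, q, strength in spec.coupled_pairs:
        letters = rng.choice(list(AMINO_ACIDS), size=4, replace=False)
        pair_states.append((p, q, strength, letters))

    rows = [consensus.copy()]
    for _ in range(spec.n_seqs - 1):
        row = consensus.copy()
        # independent substitutions
        for i in range(spec.L):
            flip = spec.conserved_flip if conserved[i] else spec.background_flip
            if rng.random() < flip:
                row[i] = _draw_background(rng, None)
        # locally correlated mutation segments (neighbour coevolution background)
        for _ in range(rng.poisson(spec.segment_rate)):
            seg_len = int(rng.integers(2, 4))
            start = int(rng.integers(0, max(spec.L - seg_len, 1)))
            for i in range(start, min(start + seg_len, spec.L)):
                if not conserved[i]:
                    row[i] = _draw_background(rng, None)
        # planted couplings overwrite their two columns
        for p, q, strength, letters in pair_states:
            if rng.random() < strength:
                s = int(rng.integers(0, 2))
                row[p], row[q] = letters[s], letters[2 + s]
            else:
                row[p] = letters[int(rng.integers(0, 2))]
                row[q] = letters[2 + int(rng.integers(0, 2))]
        rows.append(row)
    # the consensus row also needs coupled-column letters from the model
    for p, q, strength, letters in pair_states:
        rows[0][p], rows[0][q] = letters[0], letters[2]
    return Alignment(rows=["".join(r) for r in rows], reference_row=0)


# ---------------------------------------------------------------------------
# helix dimer generator
# ---------------------------------------------------------------------------

def _facing_half_angle(separation: float, d_max: float = 3.5) -> float:
    """Azimuth half-width (degrees) within which same-index C-beta pairs touch.

    For two mirrored ideal helices the closest atoms are the C-beta pair of a
    residue and its image; their distance is
    ``sqrt(sep^2 - 2*(2*R)*sep*cos(phi) + (2*R)^2)`` with R the C-beta radius
    and phi the residue azimuth measured from the inter-axis direction.
    """
    cos_arg = (separation**2 + (2 * CB_RADIUS) ** 2 - d_max**2) / (
        2 * (2 * CB_RADIUS) * separation
    )
    if cos_arg >= 1.0:
        return 0.0
    if cos_arg <= -1.0:
        return 180.0
    return float(np.degrees(np.arccos(cos_arg)))


def synth_helix_dimer(
    length: int,
    separation: float = 10.0,
    phase_deg: float = 0.0,
    antiparallel: bool = False,
    sequence: str | None = None,
    d_max: float = 3.5,
):
    """Ideal two-chain helix dimer plus the planted facing-residue mask.

    Chain B is chain A rotated 180 degrees about the membrane normal and
    shifted by ``separation`` along x, so residue i of each chain faces its
    own image.  The planted mask marks residues whose azimuth lies within the
    analytic facing half-angle at this separation, which is exactly the set
    the heavy-atom contact rule recovers.

    Returns ``(atoms, planted_mask)`` where ``atoms`` is a biotite
    :class:`AtomArray` with chains A and B.
    """
    import biotite.structure as struc

    if length < 10:
        raise errors.SpecError("helix dimer needs length >= 10")
    if separation <= CB_RADIUS:
        raise errors.SpecError(
            f"axis separation {separation} A clashes with the helix radius {CB_RADIUS} A"
        )
    if sequence is None:
        sequence = "L" * length
    if len(sequence) != length:
        raise errors.SpecError("sequence length mismatch")

    phi = np.radians(HELIX_TWIST * np.arange(length) + phase_deg)
    z = HELIX_RISE * np.arange(length, dtype=float)
    ca_a = np.column_stack([CA_RADIUS * np.cos(phi), CA_RADIUS * np.sin(phi), z])
    cb_a = np.column_stack([CB_RADIUS * np.cos(phi), CB_RADIUS * np.sin(phi), z])
    # chain B: 180 deg rotation about z, then +separation along x
    ca_b = np.column_stack([separation - ca_a[:, 0], -ca_a[:, 1], z])
    cb_b = np.column_stack([separation - cb_a[:, 0], -cb_a[:, 1], z])
    if antiparallel:
        ca_b[:, 2] = z[::-1]
        cb_b[:, 2] = z[::-1]

    three = {
        "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
        "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
        "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
        "Y": "TYR", "V": "VAL",
    }
    n_atoms = 4 * length
    atoms = struc.AtomArray(n_atoms)
    idx = 0
    for chain_id, ca, cb in (("A", ca_a, cb_a), ("B", ca_b, cb_b)):
        for i in range(length):
            for name, coord in (("CA", ca[i]), ("CB", cb[i])):
                atoms.chain_id[idx] = chain_id
                atoms.res_id[idx] = i + 1
                atoms.res_name[idx] = three[sequence[i]]
                atoms.atom_name[idx] = name
                atoms.element[idx] = "C"
                atoms.coord[idx] = coord
                idx += 1
    atoms.hetero[:] = False

    half_angle = _facing_half_angle(separation, d_max)
    azimuth = (HELIX_TWIST * np.arange(length) + phase_deg) % 360.0
    wrapped = np.minimum(azimuth, 360.0 - azimuth)
    planted_mask = wrapped < half_angle
    return atoms, planted_mask


def write_dimer_pdb(atoms, path) -> None:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# mutagenesis generator
# ---------------------------------------------------------------------------

def synth_etra_table(
    spec: FixtureSpec, tmd_id: str = "SYN", n_mut_per_pos: int = 2
) -> tuple[str, list[MutagenesisRecord]]:
    """Synthetic scanning-mutagenesis table with a planted interface.

    The wildtype signal is fixed at 1.0; interface positions receive a mean
    disruption equal to ``spec.effect_size`` and all other positions 0, each
    perturbed by Gaussian noise of sd ``spec.noise``.  Returns the wildtype
    sequence and the per-mutation records.
    """
    if spec.effect_size <= 0:
        raise errors.SpecError("effect_size must be > 0")
    rng = np.random.default_rng(spec.seed)
    sequence = "".join(_draw_background(rng, spec.L))
    interface = np.zeros(spec.L, dtype=bool)
    interface[list(spec.interface_positions)] = True
    records = []
    for pos0 in range(spec.L):
        wt = sequence[pos0]
        for _ in range(n_mut_per_pos):
            mut = "I" if wt in "GA" else "A"
            d_true = spec.effect_size if interface[pos0] else 0.0
            d = d_true + spec.noise * rng.standard_normal()
            records.append(
                MutagenesisRecord(
                    tmd_id=tmd_id, position=pos0 + 1, wt_residue=wt,
                    mut_residue=mut, w=1.0, m=1.0 - d,
                )
            )
    return sequence, records


# ---------------------------------------------------------------------------
# face masks and the multi-TMD benchmark
# ---------------------------------------------------------------------------

def helical_face_mask(
    length: int, n_interface: int, face_angle_deg: float, depth_weight: float = 0.5
) -> np.ndarray:
    """Mask of the ``n_interface`` residues closest to one helix face.

    Residue i (0-based) sits at azimuth 100 deg * i; its affinity for the
    face is ``cos(azimuth - face_angle) + depth_weight * depth(i)``, which
    yields alpha-helically periodic masks biased toward the helix centre.
    Ties are broken by ascending position.
    """
    if not 1 <= n_interface <= length:
        raise ValueError("n_interface must be in 1..length")
    azimuth = np.radians(HELIX_TWIST * np.arange(length) - face_angle_deg)
    score = np.cos(azimuth) + depth_weight * depth_profile(length)
    order = np.lexsort((np.arange(length), -score))
    mask = np.zeros(length, dtype=bool)
    mask[order[:n_interface]] = True
    return mask


def _stable_angle(key: str) -> float:
    digest = hashlib.sha256(key.encode()).hexdigest()
    return int(digest[:8], 16) % 360


def synthetic_reference_masks(total_interface: int = 304) -> dict:
    """SYNTHETIC stand-in for the reference set's interface annotations.

    The original per-residue annotations of the 50-TMD reference set are not
    distributed with this package.  This reconstruction is constrained only
    by published aggregate properties of that dataset: 304 interface residues
    in total, 3-10 per helix, alpha-helical single-face periodicity and a
    bias toward the helix centre.  Per-helix counts follow a largest-
    remainder allotment proportional to length; face azimuths derive from a
    stable per-id hash.  Use it for statistics that depend only on mask
    geometry and coverage — it carries no information about which residues
    of a given sequence are truly interfacial.
    """
    df = load_reference_table()
    lengths = df.sequence.str.len().to_numpy()
    quota = total_interface * lengths / lengths.sum()
    counts = np.clip(np.floor(quota).astype(int), 3, 10)
    remainder = quota - np.floor(quota)
    # distribute the leftover to the largest remainders, respecting the 3-10 range
    order = np.argsort(-remainder, kind="stable")
    deficit = total_interface - counts.sum()
    for idx in list(order) * 2:  # at most two passes needed
        if deficit == 0:
            break
        if deficit > 0 and counts[idx] < 10:
            counts[idx] += 1
            deficit -= 1
        elif deficit < 0 and counts[idx] > 3:
            counts[idx] -= 1
            deficit += 1
    masks = {}
    for (tmd_id, seq), n in zip(zip(df.tmd_id, df.sequence), counts):
        masks[tmd_id] = helical_face_mask(len(seq), int(n), _stable_angle(tmd_id))
    return masks


def load_synthetic_reference_records(total_interface: int = 304) -> list[TMDRecord]:
    """Reference TMDRecords carrying the synthetic interface masks."""
    from .reference import load_reference_tmds

    masks = synthetic_reference_masks(total_interface)
    records = load_reference_tmds()
    for rec in records:
        rec.interface_mask = masks[rec.id]
    return records


def synth_tmd_benchmark(
    n_tmds: int = 50,
    interface_rate: float = 0.28,
    seed: int = 0,
    n_seqs: int = 80,
):
    """Labelled multi-TMD benchmark with interface-like sequence signal.

    Each helix receives a face-periodic, centre-biased interface mask whose
    size is ``round(interface_rate * L)`` clipped to 3-10.  Interface
    positions are enriched for GxxxG pairs and small/polar residues, and
    their alignment columns are strongly conserved, while non-interface
    columns mutate freely.  Returns ``(records, alignments)`` with one
    :class:`Alignment` per TMD.
    """
    if n_tmds < 10:
        raise errors.SpecError("benchmark needs >= 10 TMDs")
    rng = np.random.default_rng(seed)
    records = []
    alignments = {}
    polarish = list("GSTANQ")
    for t in range(n_tmds):
        length = int(rng.integers(15, 31))
        n_iface = int(np.clip(round(interface_rate * length), 3, 10))
        face_angle = float(rng.uniform(0, 360))
        mask = helical_face_mask(length, n_iface, face_angle)
        consensus = _draw_background(rng, length)
        # plant GxxxG pairs on the interface face
        iface_pairs = [
            (i, i + 4) for i in range(length - 4) if mask[i] and mask[i + 4]
        ]
        for i, j in iface_pairs[:2]:
            if rng.random() < 0.7:
                consensus[i] = consensus[j] = "G"
        # bias remaining interface residues toward small/polar
        for i in np.flatnonzero(mask):
            if consensus[i] != "G" and rng.random() < 0.5:
                consensus[i] = polarish[int(rng.integers(len(polarish)))]
        rows = [consensus.copy()]
        for _ in range(n_seqs - 1):
            row = consensus.copy()
            for i in range(length):
                flip = 0.15 if mask[i] else 0.45
                if rng.random() < flip:
                    row[i] = _draw_background(rng, None)
            rows.append(row)
        tmd_id = f"SYN{t:03d}"
        records.append(
            TMDRecord(id=tmd_id, subset="ETRA", sequence="".join(consensus),
                      interface_mask=mask)
        )
        alignments[tmd_id] = Alignment(rows=["".join(r) for r in rows], reference_row=0)
    return records, alignments
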
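"""Interface truth construction for homotypic TMD dimers.

Two routes produce per-residue interface labels:

* **Mutagenesis route** (bacterial reporter assays): each point mutation's
  disruption of the dimerisation signal is ``d = (w - m) / w``; the
  per-position mean ``d_bar`` is thresholded at a fixed cutoff (default 0.24,
  chosen to yield 3-10 interface residues per helix).
* **Structural route** (NMR / X-ray dimers): a residue is interfacial when any
  pair of heavy atoms, one from each chain, lies strictly closer than 3.5 A.

The module also implements the X-ray inclusion filters (resolution <= 3.5 A,
parallel orientation, >= 4 interface residues), the A/B/C residue grouping of
helices extracted from polytopic complexes, and the i,i / i,i+-1 contact
symmetry statistic of homodimer interfaces.

Residue indices are 1-based in all public inputs and outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import errors
from .reference import AMINO_ACIDS

logger = logging.getLogger(__name__)

DEFAULT_DISRUPTION_CUTOFF = 0.24
DEFAULT_CONTACT_DISTANCE = 3.5  # Angstrom, strict upper bound on heavy-atom distance


class Subset(str, Enum):
    ETRA = "ETRA"
    NMR = "NMR"
    XRAY = "XRAY"


class ResidueGroup(str, Enum):
    """Residue roles of a TM helix inside a polytopic complex."""

    HOMOTYPIC = "A"  # contacts the identical partner helix
    LIPID = "B"  # no protein contact; assumed lipid-facing
    HETEROTYPIC = "C"  # contacts a different chain (folding contact)


@dataclass
class TMDRecord:
    """One transmembrane helix with optional interface annotation."""

    id: str
    subset: str
    sequence: str
    interface_mask: np.ndarray | None = None

    def __post_init__(self):
        self.subset = Subset(self.subset).value
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"{self.id}: non-canonical residues {sorted(bad)}")
        if self.interface_mask is not None:
            self.interface_mask = np.asarray(self.interface_mask, dtype=bool)
            if self.interface_mask.shape != (len(self.sequence),):
                raise ValueError(f"{self.id}: interface mask length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MutagenesisRecord:
    """One point mutation and its dimerisation signals (arbitrary units)."""

    tmd_id: str
    position: int  # 1-based within the TMD
    wt_residue: str
    mut_residue: str
    w: float  # wildtype signal, > 0
    m: float  # mutant signal, >= 0

    def __post_init__(self):
        if not np.isfinite(self.w) or self.w <= 0:
            raise errors.InvalidSignalError(
                f"{self.tmd_id} pos {self.position}: wildtype signal must be > 0, got {self.w}"
            )
        if self.position < 1:
            raise IndexError(f"position must be >= 1, got {self.position}")

    @property
    def disruption(self) -> float:
        """d = (w - m) / w; positive when the mutation weakens dimerisation."""
        return (self.w - self.m) / self.w


@dataclass
class PositionDisruption:
    """Per-position summary of mutational disruption."""

    position: int
    d_values: list[float]

    @property
    def d_bar(self) -> float:
        return float(np.mean(self.d_values))

    @property
    def n(self) -> int:
        return len(self.d_values)


@dataclass
class ContactMap:
    """Inter-chain residue contacts of a helix dimer (1-based indices)."""

    pairs: set = field(default_factory=set)
    d_max: float = DEFAULT_CONTACT_DISTANCE

    def __post_init__(self):
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        self.pairs = {(int(i), int(j)) for i, j in self.pairs}


# ---------------------------------------------------------------------------
# mutagenesis route
# ---------------------------------------------------------------------------

def position_disruption(
    records: list[MutagenesisRecord], sequence: str | None = None
) -> list[PositionDisruption]:
    """Aggregate per-mutation disruptions into per-position means.

    All records must belong to one TMD.  When ``sequence`` is given, positions
    are bounds-checked and wildtype residues verified against it.  Positions
    with no mutations are absent from the output.
    """
    if not records:
        raise errors.EmptyDataError("no mutagenesis records given")
    ids = {r.tmd_id for r in records}
    if len(ids) != 1:
        raise ValueError(f"records span multiple TMDs: {sorted(ids)}")
    by_pos: dict[int, list[float]] = {}
    for r in records:
        if sequence is not None:
            if r.position > len(sequence):
                raise IndexError(
                    f"{r.tmd_id}: position {r.position} outside TMD of length {len(sequence)}"
                )
            if sequence[r.position - 1] != r.wt_residue:
                raise ValueError(
                    f"{r.tmd_id} pos {r.position}: wildtype {r.wt_residue!r} does not "
                    f"match sequence residue {sequence[r.position - 1]!r}"
                )
        by_pos.setdefault(r.position, []).append(r.disruption)
    return [PositionDisruption(p, ds) for p, ds in sorted(by_pos.items())]


def call_interface_etra(
    positions: list[PositionDisruption],
    length: int,
    cutoff: float = DEFAULT_DISRUPTION_CUTOFF,
) -> np.ndarray:
    """Interface mask from per-position mean disruption.

    ``mask[i]`` is True iff ``d_bar >= cutoff`` at position ``i+1`` (boundary
    inclusive).  Unmutated positions are labelled non-interface.
    """
    if not positions:
        raise errors.EmptyDataError("no position disruptions given")
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    mask = np.zeros(length, dtype=bool)
    for p in positions:
        if not 1 <= p.position <= length:
            raise IndexError(f"position {p.position} outside 1..{length}")
        if p.d_bar >= cutoff:
            mask[p.position - 1] = True
    return mask


# ---------------------------------------------------------------------------
# structural route
# ---------------------------------------------------------------------------

def _heavy(atoms):
    element = np.char.upper(atoms.element.astype("U3"))
    return atoms[element != "H"]


def _residue_index_map(atoms) -> np.ndarray:
    """Map each atom to a 1-based residue rank within its chain."""
    import biotite.structure as struc

    starts = struc.get_residue_starts(atoms)
    ranks = np.zeros(atoms.array_length(), dtype=int)
    for rank, start in enumerate(starts, start=1):
        ranks[start:] = rank
    return ranks


def interchain_contacts(chain_a, chain_b, d_max: float = DEFAULT_CONTACT_DISTANCE) -> ContactMap:
    """Residue pairs with any heavy-atom pair strictly closer than ``d_max``.

    ``chain_a`` and ``chain_b`` are biotite :class:`AtomArray` objects.
    Hydrogens are removed before the distance scan; residues lacking
    coordinates simply contribute no atoms.  Candidate atom pairs are found
    with a k-d tree and filtered with a strict ``<`` comparison.
    """
    a = _heavy(chain_a)
    b = _heavy(chain_b)
    if a.array_length() == 0 or b.array_length() == 0:
        raise errors.EmptyStructureError("a chain contains no heavy atoms")
    ranks_a = _residue_index_map(a)
    ranks_b = _residue_index_map(b)
    tree = cKDTree(b.coord)
    pairs = set()
    neighbours = tree.query_ball_point(a.coord, r=d_max)
    for ia, idxs in enumerate(neighbours):
        if not idxs:
            continue
        d = np.linalg.norm(b.coord[idxs] - a.coord[ia], axis=1)
        for ib, dist in zip(idxs, d):
            if dist < d_max:  # strict: ties at exactly d_max are not contacts
                pairs.add((int(ranks_a[ia]), int(ranks_b[ib])))
    return ContactMap(pairs=pairs, d_max=d_max)


def call_interface_structure(cmap: ContactMap, length: int) -> np.ndarray:
    """Interface mask: residues appearing in any inter-chain contact pair.

    For a homodimer both chain roles are equivalent, so a residue index seen
    on either side of a pair is marked interfacial.
    """
    mask = np.zeros(length, dtype=bool)
    for i, j in cmap.pairs:
        for idx in (i, j):
            if not 1 <= idx <= length:
                raise IndexError(f"contact index {idx} outside 1..{length}")
            mask[idx - 1] = True
    return mask


def helix_orientation(ca_coords_a: np.ndarray, ca_coords_b: np.ndarray) -> str:
    """'parallel' or 'antiparallel' from principal-component helix axes.

    The axis of each helix is the first principal component of its C-alpha
    coordinates, oriented from the first toward the last residue; the sign of
    the dot product decides the relative orientation.
    """
    axes = []
    for ca in (np.asarray(ca_coords_a), np.asarray(ca_coords_b)):
        if len(ca) < 3:
            raise errors.OrientationError("need >= 3 C-alpha atoms per helix")
        centred = ca - ca.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        axis = vt[0]
        if np.dot(ca[-1] - ca[0], axis) < 0:
            axis = -axis
        axes.append(axis)
    dot = float(np.dot(axes[0], axes[1]))
    if abs(dot) < 1e-8:
        raise errors.OrientationError("helix axes are orthogonal; orientation undetermined")
    return "parallel" if dot > 0 else "antiparallel"


def xray_inclusion_filter(
    resolution: float, orientation: str, n_interface: int
) -> tuple[bool, str]:
    """Apply the X-ray dataset inclusion rules.

    Keep iff resolution <= 3.5 A, the pair is parallel, and it has at least
    four interface residues.  Returns ``(keep, reason)`` where ``reason`` is
    'ok' or the first failed rule.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if orientation not in ("parallel", "antiparallel"):
        raise errors.OrientationError(f"unknown orientation {orientation!r}")
    if resolution > 3.5:
        return False, "resolution"
    if orientation != "parallel":
        return False, "orientation"
    if n_interface < 4:
        return False, "too_few_interface_residues"
    return True, "ok"


def classify_residue_groups(
    tmd_chain, partner_chain, other_chains=(), d_max: float = DEFAULT_CONTACT_DISTANCE
) -> np.ndarray:
    """Assign each TMD residue to group A (homotypic), C (heterotypic) or B (lipid).

    Group A: any heavy-atom contact (< d_max) with the identical partner
    chain.  Group C: no homotypic contact but a contact with some other
    protein chain of the complex.  Group B: no protein contact at all.
    """
    if partner_chain is None:
        raise errors.ConfigurationError("homotypic partner chain is required")
    import biotite.structure as struc

    length = struc.get_residue_count(_heavy(tmd_chain))
    homo = call_interface_structure(interchain_contacts(tmd_chain, partner_chain, d_max), length)
    hetero = np.zeros(length, dtype=bool)
    for other in other_chains:
        if _heavy(other).array_length() == 0:
            continue
        cmap = interchain_contacts(tmd_chain, other, d_max)
        for i, _ in cmap.pairs:
            hetero[i - 1] = True
    groups = np.full(length, ResidueGroup.LIPID.value, dtype="U1")
    groups[hetero] = ResidueGroup.HETEROTYPIC.value
    groups[homo] = ResidueGroup.HOMOTYPIC.value
    return groups


def contact_symmetry_fraction(cmap: ContactMap, interface_mask: np.ndarray) -> float:
    """Fraction of interface residues with an i,i or i,i+-1 contact.

    Quantifies the two-fold symmetry of a homodimer interface: a residue
    counts as symmetric when it touches its own image or a direct neighbour
    of its image in the opposing chain.
    """
    if not cmap.pairs:
        raise errors.EmptyDataError("contact map is empty")
    interface = np.flatnonzero(np.asarray(interface_mask, dtype=bool)) + 1
    if interface.size == 0:
        raise errors.UndefinedMetricError("no interface residues; fraction undefined")
    symmetric_partners = {}
    for i, j in cmap.pairs:
        for a, b in ((i, j), (j, i)):
            symmetric_partners.setdefault(a, set()).add(b)
    hits = sum(
        1
        for i in interface
        if any(abs(i - j) <= 1 for j in symmetric_partners.get(i, ()))
    )
    return hits / interface.size


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

MUTAGENESIS_COLUMNS = ["tmd_id", "position", "wt", "mut", "w", "m"]


def read_mutagenesis_tsv(path) -> list[MutagenesisRecord]:
    """Read a scanning-mutagenesis table (TSV with header tmd_id position wt mut w m)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(MUTAGENESIS_COLUMNS) - set(df.columns)
    if missing:
        raise errors.SchemaError(f"mutagenesis table missing columns {sorted(missing)}")
    return [
        MutagenesisRecord(
            tmd_id=str(r.tmd_id),
            position=int(r.position),
            wt_residue=str(r.wt),
            mut_residue=str(r.mut),
            w=float(r.w),
            m=float(r.m),
        )
        for r in df.itertuples()
    ]


def write_mutagenesis_tsv(records: list[MutagenesisRecord], path) -> None:
    df = pd.DataFrame(
        [(r.tmd_id, r.position, r.wt_residue, r.mut_residue, r.w, r.m) for r in records],
        columns=MUTAGENESIS_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_interface_tsv(record: TMDRecord, path, positions=None) -> None:
    """Write a per-residue interface mask with optional disruption summaries."""
    if record.interface_mask is None:
        raise errors.EmptyDataError(f"{record.id}: no interface mask to write")
    by_pos = {p.position: p for p in positions} if positions else {}
    rows = []
    for i, (res, flag) in enumerate(zip(record.sequence, record.interface_mask), start=1):
        p = by_pos.get(i)
        rows.append(
            (record.id, i, res, int(flag),
             round(p.d_bar, 6) if p else "", p.n if p else "")
        )
    pd.DataFrame(
        rows, columns=["tmd_id", "position", "residue", "interface", "d_bar", "n"]
    ).to_csv(path, sep="\t", index=False)
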
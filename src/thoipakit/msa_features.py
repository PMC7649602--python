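"""Alignment- and sequence-derived residue features for TM helices.

Feature families (names in parentheses are the table-column prefixes):

* PSSM fractions — per-column amino-acid proportions over the valid homologue
  rows, plus composite fractions for small, strongly polar, aromatic and
  aliphatic residues and the gap fraction (25 columns).
* Conservation — Shannon entropy H (bits) of the column and the inverted,
  normalised form C = 1 - H / log2(20), which is 1 for a perfectly conserved
  column and 0 for a uniform one, plus gap-aware and windowed variants
  (8 columns).
* Polarity — mean sign-flipped GES transfer free energy over the column
  (higher = more polar) and its value relative to the six flanking positions,
  plus query-sequence variants and the face scores below (8 columns).
* Position — residue depth in the bilayer (0 at the termini, 1 at the helix
  centre), the normalised position and whole-TMD summaries (5 columns).
* Motif / physical flags — membership of GxxxG, (small)xxx(small) and
  (polar)xxx(polar) pairs at i,i+4 spacing, and beta-branched / small residue
  indicators.

A simplified LIPS-style score ranks the seven overlapping helix faces (one
face per start offset on a two-turn, 7-residue repeat; ~100 degrees of
azimuth per residue) by combined conservation and polarity of their member
residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import errors
from .reference import (
    ALIPHATIC,
    AMINO_ACIDS,
    AROMATIC,
    BRANCHED,
    SMALL,
    STRONGLY_POLAR,
    load_ges_scale,
)

GAP = "-"
MAX_ENTROPY_BITS = float(np.log2(20))
#: Homologue rows with more than this gap fraction inside the TMD span are
#: flagged invalid and excluded from column statistics.
MAX_ROW_GAP_FRACTION = 0.3

PSSM_COMPOSITES = {
    "small": SMALL,
    "strongly_polar": STRONGLY_POLAR,
    "aromatic": AROMATIC,
    "aliphatic": ALIPHATIC,
}


@dataclass
class Alignment:
    """A homologue MSA anchored on an ungapped reference row.

    ``tmd_span`` is half-open and 0-based on the *reference sequence*
    coordinates (gaps in the reference row do not count).
    """

    rows: list[str]
    reference_row: int = 0
    tmd_span: tuple[int, int] | None = None
    ids: list[str] | None = None
    valid_row_flags: np.ndarray = field(init=False)

    def __post_init__(self):
        if not self.rows:
            raise errors.EmptyDataError("alignment has no rows")
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ValueError("alignment rows have unequal lengths")
        ref = self.rows[self.reference_row]
        ref_len = len(ref) - ref.count(GAP)
        if self.tmd_span is None:
            self.tmd_span = (0, ref_len)
        start, end = self.tmd_span
        if not (0 <= start < end <= ref_len):
            raise ValueError(f"tmd_span {self.tmd_span} outside reference of length {ref_len}")
        cols = self.tmd_columns()
        sub = np.array([[r[c] for c in cols] for r in self.rows], dtype="U1")
        gap_frac = (sub == GAP).mean(axis=1)
        flags = gap_frac <= MAX_ROW_GAP_FRACTION
        flags[self.reference_row] = True
        self.valid_row_flags = flags

    def tmd_columns(self) -> list[int]:
        """Alignment column indices covering the TMD span of the reference."""
        ref = self.rows[self.reference_row]
        start, end = self.tmd_span
        cols = []
        seq_i = 0
        for col, ch in enumerate(ref):
            if ch != GAP:
                if start <= seq_i < end:
                    cols.append(col)
                seq_i += 1
        return cols

    @property
    def tmd_sequence(self) -> str:
        ref = self.rows[self.reference_row]
        return "".join(ref[c] for c in self.tmd_columns())

    @property
    def n_valid(self) -> int:
        return int(self.valid_row_flags.sum())

    def tmd_matrix(self, valid_only: bool = True) -> np.ndarray:
        """Character matrix (rows x TMD columns)."""
        cols = self.tmd_columns()
        mat = np.array([[r[c] for c in cols] for r in self.rows], dtype="U1")
        if valid_only:
            mat = mat[self.valid_row_flags]
        return mat


def read_alignment(path, reference_id: str | None = None, tmd_span=None) -> Alignment:
    """Read an aligned FASTA; the reference is the named row or the first one."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise errors.EmptyDataError(f"no sequences in {path}")
    ids = [r.id for r in records]
    ref_idx = 0 if reference_id is None else ids.index(reference_id)
    return Alignment(
        rows=[str(r.seq).upper() for r in records],
        reference_row=ref_idx,
        tmd_span=tmd_span,
        ids=ids,
    )


# ---------------------------------------------------------------------------
# PSSM and conservation
# ---------------------------------------------------------------------------

def build_pssm(aln: Alignment) -> pd.DataFrame:
    """Per-column residue fractions over valid rows (25 columns).

    Amino-acid fractions use the non-gap count as denominator, so the 20
    fractions of any column with at least one residue sum to 1; ``gap`` is
    the gap fraction over valid rows.  An all-gap column has aa fractions 0
    and gap fraction 1.
    """
    mat = aln.tmd_matrix()
    n_pos = mat.shape[1]
    out = pd.DataFrame(
        0.0, index=pd.RangeIndex(n_pos, name="position0"),
        columns=list(AMINO_ACIDS) + list(PSSM_COMPOSITES) + ["gap"],
    )
    for i in range(n_pos):
        col = mat[:, i]
        non_gap = col[col != GAP]
        out.loc[i, "gap"] = 1.0 - non_gap.size / col.size
        if non_gap.size:
            vals, counts = np.unique(non_gap, return_counts=True)
            for v, c in zip(vals, counts):
                out.loc[i, v] = c / non_gap.size
    for name, members in PSSM_COMPOSITES.items():
        out[name] = out[list(members)].sum(axis=1)
    return out


def column_conservation(fractions) -> tuple[float, float]:
    """(H bits, C) for one column given its 20 residue fractions.

    H is the Shannon entropy of the residue distribution; C = 1 - H/log2(20)
    inverts it so values rise with conservation.  An all-gap column (zero
    fractions) yields ``(nan, nan)``.
    """
    p = np.asarray([fractions[a] for a in AMINO_ACIDS], dtype=float)
    total = p.sum()
    if total <= 0:
        return float("nan"), float("nan")
    p = p / total
    p = p[p > 0]
    h = float(-(p * np.log2(p)).sum())
    return h, 1.0 - h / MAX_ENTROPY_BITS


def _relative_to_flanks(values: np.ndarray, flank: int = 3) -> np.ndarray:
    """value minus the mean over up to ``flank`` positions on each side."""
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        neigh = [values[j] for j in range(max(0, i - flank), min(n, i + flank + 1)) if j != i]
        out[i] = values[i] - float(np.mean(neigh)) if neigh else 0.0
    return out


def conservation_features(aln: Alignment, pssm: pd.DataFrame | None = None) -> pd.DataFrame:
    """The 8-column conservation family.

    ``entropy``/``conservation`` ignore gaps; the ``_gaps`` variants treat the
    gap as a 21st state; ``majority_fraction`` is the modal residue fraction;
    ``ref_identity`` the fraction of valid rows matching the reference
    residue; the ``_rel`` variants subtract the mean of the six flanking
    positions.
    """
    if pssm is None:
        pssm = build_pssm(aln)
    n = len(pssm)
    h = np.empty(n)
    c = np.empty(n)
    hg = np.empty(n)
    cg = np.empty(n)
    for i in range(n):
        h[i], c[i] = column_conservation(pssm.loc[i])
        pg = np.append(
            pssm.loc[i, list(AMINO_ACIDS)].to_numpy(float) * (1 - pssm.loc[i, "gap"]),
            pssm.loc[i, "gap"],
        )
        pg = pg[pg > 0]
        hg[i] = -(pg * np.log2(pg)).sum()
        cg[i] = 1.0 - hg[i] / np.log2(21)
    ref = np.array(list(aln.tmd_sequence))
    mat = aln.tmd_matrix()
    ref_identity = (mat == ref[None, :]).mean(axis=0)
    majority = pssm[list(AMINO_ACIDS)].max(axis=1).to_numpy()
    return pd.DataFrame(
        {
            "entropy": h,
            "conservation": c,
            "entropy_gaps": hg,
            "conservation_gaps": cg,
            "majority_fraction": majority,
            "ref_identity": ref_identity,
            "conservation_rel": _relative_to_flanks(np.nan_to_num(c)),
            "entropy_rel": _relative_to_flanks(np.nan_to_num(h)),
        }
    )


# ---------------------------------------------------------------------------
# polarity
# ---------------------------------------------------------------------------

def polarity_features(aln: Alignment, scale: dict | None = None) -> pd.DataFrame:
    """Mean-MSA and query-sequence polarity, absolute and relative to flanks.

    Polarity is the negated GES transfer free energy, so Arg scores high and
    Phe low; ``relative_polarity`` subtracts the mean over the surrounding six
    residues (three per side, truncated at the termini).
    """
    if scale is None:
        scale = load_ges_scale()
    missing = set(AMINO_ACIDS) - set(scale)
    if missing:
        raise errors.ConfigurationError(f"hydrophobicity scale missing {sorted(missing)}")
    polar = {a: -scale[a] for a in AMINO_ACIDS}
    mat = aln.tmd_matrix()
    n = mat.shape[1]
    p = np.empty(n)
    for i in range(n):
        col = [polar[ch] for ch in mat[:, i] if ch != GAP]
        p[i] = float(np.mean(col)) if col else np.nan
    query = np.array([polar[ch] for ch in aln.tmd_sequence])
    return pd.DataFrame(
        {
            "polarity": p,
            "relative_polarity": _relative_to_flanks(np.nan_to_num(p)),
            "polarity_query": query,
            "relative_polarity_query": _relative_to_flanks(query),
        }
    )


# ---------------------------------------------------------------------------
# position / motifs / physical
# ---------------------------------------------------------------------------

def residue_depth(i: int, length: int) -> float:
    """Depth in the bilayer: 0 at the first/last residue, 1 at the centre.

    ``depth = 1 - |2 i - (L - 1)| / (L - 1)`` for 0-based position ``i``.
    """
    if length < 2:
        raise errors.InsufficientLengthError("TMD length must be >= 2")
    if not 0 <= i < length:
        raise IndexError(f"position {i} outside 0..{length - 1}")
    return 1.0 - abs(2 * i - (length - 1)) / (length - 1)


def depth_profile(length: int) -> np.ndarray:
    return np.array([residue_depth(i, length) for i in range(length)])


def motif_pair_positions(seq: str, members: frozenset) -> list[tuple[int, int]]:
    """0-based (i, i+4) pairs whose two defining residues are both in ``members``.

    Overlapping instances all count (GxxxGxxxG contains two GxxxG pairs).
    """
    return [
        (i, i + 4)
        for i in range(len(seq) - 4)
        if seq[i] in members and seq[i + 4] in members
    ]


def motif_and_physical_flags(seq: str) -> pd.DataFrame:
    """Per-residue motif membership and physical flags (booleans)."""
    n = len(seq)
    flags = {
        "in_gxxxg": np.zeros(n, bool),
        "in_smallxxxsmall": np.zeros(n, bool),
        "in_polarxxxpolar": np.zeros(n, bool),
    }
    for col, members in (
        ("in_gxxxg", frozenset("G")),
        ("in_smallxxxsmall", SMALL),
        ("in_polarxxxpolar", STRONGLY_POLAR),
    ):
        for i, j in motif_pair_positions(seq, members):
            flags[col][i] = flags[col][j] = True
    flags["is_branched"] = np.array([ch in BRANCHED for ch in seq])
    flags["is_small"] = np.array([ch in SMALL for ch in seq])
    flags["is_strongly_polar"] = np.array([ch in STRONGLY_POLAR for ch in seq])
    return pd.DataFrame(flags)


# ---------------------------------------------------------------------------
# LIPS-style face scores
# ---------------------------------------------------------------------------

N_FACES = 7
_FACE_OFFSETS = (0, 3, 4)  # two-turn helical repeat: i, i+3, i+4 (+7, +10, +11, ...)


def face_members(face: int, length: int) -> list[int]:
    """0-based residue positions belonging to helix face ``face`` (0..6)."""
    return [i for i in range(length) if (i - face) % N_FACES in _FACE_OFFSETS]


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.nan_to_num(np.asarray(v, dtype=float))
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def lips_face_scores(aln: Alignment) -> pd.DataFrame:
    """Score the seven helix faces by combined conservation and polarity.

    Faces are scored as the mean of z-scored conservation plus z-scored
    polarity over their member residues.  Each residue belongs to three
    faces; its ``lips_score`` is the score of the best of those, and
    ``lips_top_face`` marks membership of the globally top-ranked face.
    Ties are broken by the lowest face index.
    """
    length = len(aln.tmd_sequence)
    if length < N_FACES:
        raise errors.InsufficientLengthError(
            f"TMD of length {length} too short for face assignment (need >= {N_FACES})"
        )
    pssm = build_pssm(aln)
    cons = conservation_features(aln, pssm)["conservation"].to_numpy()
    pol = polarity_features(aln)["polarity"].to_numpy()
    combined = _zscore(cons) + _zscore(pol)
    face_score = np.array([combined[face_members(f, length)].mean() for f in range(N_FACES)])
    best_face = int(np.argmax(face_score))  # argmax takes the lowest index on ties
    per_res_score = np.empty(length)
    per_res_cons = np.empty(length)
    per_res_pol = np.empty(length)
    membership = [face_members(f, length) for f in range(N_FACES)]
    for i in range(length):
        faces_of_i = [f for f in range(N_FACES) if i in membership[f]]
        best = faces_of_i[int(np.argmax([face_score[f] for f in faces_of_i]))]
        per_res_score[i] = face_score[best]
        per_res_cons[i] = np.nan_to_num(cons)[membership[best]].mean()
        per_res_pol[i] = np.nan_to_num(pol)[membership[best]].mean()
    return pd.DataFrame(
        {
            "lips_score": per_res_score,
            "lips_conservation": per_res_cons,
            "lips_polarity": per_res_pol,
            "lips_top_face": np.array([i in membership[best_face] for i in range(length)]),
        }
    )


def rank_faces(aln: Alignment) -> np.ndarray:
    """Face indices sorted best-first (ties: lowest index first)."""
    length = len(aln.tmd_sequence)
    pssm = build_pssm(aln)
    cons = conservation_features(aln, pssm)["conservation"].to_numpy()
    pol = polarity_features(aln)["polarity"].to_numpy()
    combined = _zscore(cons) + _zscore(pol)
    scores = np.array([combined[face_members(f, length)].mean() for f in range(N_FACES)])
    return np.argsort(-scores, kind="stable")
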
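"""Packaged reference data: the 50-TMD homotypic dimer set and the GES scale.

The sequence set covers 50 non-homologous single-pass transmembrane helices
whose self-interaction interfaces were characterised by bacterial reporter
assays (ETRA: ToxR/TOXCAT/GALLEX-type), solution NMR, or crystallography /
high-resolution EM.  It is shipped as a plain TSV and loaded into
:class:`~thoipakit.datasets.TMDRecord` objects.

The original per-residue interface annotations are not distributed with this
package; a synthetic stand-in constrained by the published aggregate census is
available from :func:`thoipakit.synthetic_fixtures.synthetic_reference_masks`.
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Small residues forming (small)xxx(small) packing motifs.
SMALL = frozenset("GASC")
#: Strongly polar residues (Asp, Glu, Lys, Arg, Asn, Gln, His).
STRONGLY_POLAR = frozenset("DEKRNQH")
#: Aromatic residues.
AROMATIC = frozenset("FWY")
#: Aliphatic residues.
ALIPHATIC = frozenset("ILV")
#: Beta-branched residues (restricted side-chain rotamers).
BRANCHED = frozenset("IVT")


def _data_path(name: str):
    return importlib.resources.files("thoipakit.data") / name


@lru_cache(maxsize=1)
def load_reference_table() -> pd.DataFrame:
    """Return the 50-TMD reference set as a DataFrame.

    Columns: ``number, tmd_id, protein, subset, blind_test, sequence``.
    """
    with importlib.resources.as_file(_data_path("table1_sequences.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"blind_test": bool})
    return df


def load_reference_tmds():
    """Return the reference set as a list of :class:`TMDRecord` (no masks)."""
    from .datasets import TMDRecord

    df = load_reference_table()
    return [
        TMDRecord(id=row.tmd_id, subset=row.subset, sequence=row.sequence)
        for row in df.itertuples()
    ]


def blind_test_ids() -> frozenset:
    """IDs of the 10 TMDs held out for blind validation."""
    df = load_reference_table()
    return frozenset(df.loc[df.blind_test, "tmd_id"])


@lru_cache(maxsize=1)
def load_ges_scale() -> dict:
    """GES transfer free energies (kcal/mol), residue -> value.

    Positive values are hydrophobic; polarity features negate the scale so
    that larger numbers mean more polar.
    """
    with importlib.resources.as_file(_data_path("ges_scale.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    scale = dict(zip(df.residue, df.transfer_free_energy.astype(float)))
    if set(scale) != set(AMINO_ACIDS):
        raise ValueError("GES scale must cover exactly the 20 canonical residues")
    return scale
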
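"""Residue-pair dataset construction for dimer interface prediction.

From per-residue records (chain, 1-based sequence index, a representative
atom's 3-D coordinate in Angstrom, and 9 physicochemical / geometric
features) this module builds the ordered, labelled L x 18 pair matrices the
network consumes:

1. cross-chain pairing of every receptor residue with every ligand residue
   (the total count is the TNRP of the dimer);
2. interface labelling — a pair is an interface pair iff the contact area
   of its two residues, taken from different monomers, is strictly positive;
3. distance-based negative reduction: the k smallest-distance pairs seed
   windows of ``window`` consecutive residues centred on each anchor residue
   in each chain (3 x 3 = 9 candidate pairs per anchor by default,
   truncated at chain ends, de-duplicated), which tames the extreme
   label imbalance while keeping the data sequentially ordered;
4. matrix assembly and a seeded 6:2:2 dimer-level split.

The representative atom is whatever coordinate the table provides (C-alpha
recommended); computing the 9 features themselves from structures is out of
scope — they arrive precomputed in the table.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, SchemaError, ValidationError

__all__ = [
    "FEATURE_NAMES",
    "RESIDUE_COLUMNS",
    "ResidueRecord",
    "PairExample",
    "DimerPairSet",
    "DatasetSplit",
    "load_residue_table",
    "write_residue_table",
    "load_contact_table",
    "write_contact_table",
    "build_cross_pairs",
    "label_interface",
    "reduce_negatives",
    "assemble_matrix",
    "split_dimers",
]

#: The 9 per-residue features, in storage order: interior contact area,
#: exterior contact area, exterior void area, absolute and relative exterior
#: solvent-accessible area, two hydropathy indices, two pKa variants.
FEATURE_NAMES = ("IC", "EC", "EV", "AESA", "RESA", "H1", "H2", "pKa1", "pKa2")

RESIDUE_COLUMNS = ("chain", "residue_index", "x", "y", "z") + FEATURE_NAMES

CONTACT_COLUMNS = ("receptor_index", "ligand_index", "area")


@dataclass(frozen=True)
class ResidueRecord:
    """One residue: chain id, 1-based sequence index, representative-atom
    coordinate (Angstrom) and the 9-feature vector."""

    chain: str
    index: int
    coord: tuple[float, float, float]
    features: tuple[float, ...]

    def __post_init__(self):
        if len(self.features) != len(FEATURE_NAMES):
            raise ValidationError(
                f"residue needs exactly {len(FEATURE_NAMES)} features, "
                f"got {len(self.features)}")
        vals = list(self.coord) + list(self.features)
        if not np.all(np.isfinite(vals)):
            raise ValidationError(
                f"residue {self.chain}:{self.index} has non-finite values")


@dataclass
class PairExample:
    """A cross-chain residue pair: receptor features occupy feature slots
    0-8, ligand features slots 9-17; distance is the Euclidean distance of
    the representative atoms in Angstrom."""

    receptor: ResidueRecord
    ligand: ResidueRecord
    features: np.ndarray
    distance: float
    label: Optional[int] = None

    @property
    def key(self) -> tuple[int, int]:
        return (self.receptor.index, self.ligand.index)


@dataclass
class DimerPairSet:
    """One dimer's ordered pair examples plus the total candidate pair count
    (TNRP) before any reduction."""

    dimer_id: str
    pairs: list
    tnrp: int

    def __post_init__(self):
        if len(self.pairs) < 1:
            raise ValidationError("a dimer pair set needs at least one pair")

    def __len__(self) -> int:
        return len(self.pairs)

    def matrix(self) -> np.ndarray:
        m, _ = assemble_matrix(self)
        return m

    def labels(self) -> np.ndarray:
        _, y = assemble_matrix(self)
        return y


@dataclass
class DatasetSplit:
    train: list
    validation: list
    test: list
    ratio: tuple
    seed: int


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def _records_from_frame(df: pd.DataFrame) -> dict[str, list]:
    chains: dict[str, list] = {}
    feature_cols = list(FEATURE_NAMES)
    n_dropped = 0
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        vals = [row[c] for c in feature_cols]
        coord = (row["x"], row["y"], row["z"])
        if any(pd.isna(v) for v in list(vals) + list(coord)):
            n_dropped += 1
            warnings.warn(
                f"residue {row['chain']}:{row['residue_index']} (line {line_no}) "
                "has missing values and was dropped; its pairs will be excluded",
                stacklevel=2)
            continue
        rec = ResidueRecord(chain=str(row["chain"]),
                            index=int(row["residue_index"]),
                            coord=tuple(float(v) for v in coord),
                            features=tuple(float(v) for v in vals))
        chains.setdefault(rec.chain, []).append(rec)
    for recs in chains.values():
        recs.sort(key=lambda r: r.index)
    return chains


def load_residue_table(path, dialect: str = "\t") -> dict[str, list]:
    """Read a delimited residue table into per-chain record lists.

    The header must name exactly the documented columns (chain,
    residue_index, x, y, z and the 9 features).  Residues with any missing
    value are dropped with a warning — downstream, their pairs simply never
    exist.  A header-only file yields an empty dict.
    """
    try:
        df = pd.read_csv(path, sep=dialect, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, expected a residue-table header")
    except (pd.errors.ParserError, ValueError) as e:
        raise SchemaError(f"{path}: malformed residue table: {e}") from None
    missing = set(RESIDUE_COLUMNS) - set(df.columns)
    extra = set(df.columns) - set(RESIDUE_COLUMNS)
    if missing or extra:
        raise SchemaError(
            f"{path}: unexpected residue-table schema "
            f"(missing {sorted(missing)}, unknown {sorted(extra)})")
    try:
        return _records_from_frame(df)
    except (TypeError, ValueError) as e:
        raise SchemaError(f"{path}: malformed residue table: {e}") from None


def write_residue_table(path, chains: Mapping[str, Sequence[ResidueRecord]],
                        dialect: str = "\t") -> None:
    """Write per-chain records back to the canonical delimited layout (the
    inverse of :func:`load_residue_table`; a load/write cycle is bytewise
    stable)."""
    rows = []
    for chain in chains:
        for r in chains[chain]:
            rows.append([r.chain, r.index, *r.coord, *r.features])
    df = pd.DataFrame(rows, columns=list(RESIDUE_COLUMNS))
    df.to_csv(path, sep=dialect, index=False)


def load_contact_table(path, dialect: str = "\t") -> dict[tuple[int, int], float]:
    """Read a contact-area table keyed by (receptor_index, ligand_index)."""
    df = pd.read_csv(path, sep=dialect, float_precision="round_trip")
    if set(df.columns) != set(CONTACT_COLUMNS):
        raise SchemaError(f"{path}: expected columns {CONTACT_COLUMNS}")
    return {(int(r), int(l)): float(a)
            for r, l, a in df[list(CONTACT_COLUMNS)].itertuples(index=False)}


def write_contact_table(path, areas: Mapping[tuple[int, int], float],
                        dialect: str = "\t") -> None:
    rows = [[r, l, a] for (r, l), a in sorted(areas.items())]
    pd.DataFrame(rows, columns=list(CONTACT_COLUMNS)).to_csv(
        path, sep=dialect, index=False)


# ---------------------------------------------------------------------------
# Pairing, labelling, reduction
# ---------------------------------------------------------------------------

def build_cross_pairs(receptor: Sequence[ResidueRecord],
                      ligand: Sequence[ResidueRecord]) -> list:
    """All |receptor| x |ligand| cross-chain pairs, unlabeled.

    The 18-feature vector concatenates receptor features (slots 0-8) then
    ligand features (slots 9-17); the distance is the Euclidean distance of
    the two representative atoms.
    """
    if not receptor or not ligand:
        raise ValidationError("both chains must be non-empty")
    pairs = []
    for r in receptor:
        rc = np.asarray(r.coord)
        rf = np.asarray(r.features)
        for l in ligand:
            d = float(np.linalg.norm(rc - np.asarray(l.coord)))
            pairs.append(PairExample(
                receptor=r, ligand=l,
                features=np.concatenate([rf, np.asarray(l.features)]),
                distance=d))
    return pairs


def label_interface(pairs: Sequence[PairExample],
                    contact_area_table: Mapping[tuple[int, int], float]) -> list:
    """Label each pair: 1 iff the contact area of its two residues (from the
    two different monomers) is strictly positive; pairs absent from the
    table get label 0."""
    for key, area in contact_area_table.items():
        if area < 0:
            raise ValidationError(f"negative contact area for pair {key}")
    out = []
    for p in pairs:
        area = contact_area_table.get(p.key, 0.0)
        out.append(PairExample(receptor=p.receptor, ligand=p.ligand,
                               features=p.features, distance=p.distance,
                               label=int(area > 0)))
    return out


def reduce_negatives(pairs: Sequence[PairExample], anchors_k: Optional[int] = None,
                     window: int = 3, dimer_id: str = "dimer") -> DimerPairSet:
    """Distance-based negative reduction.

    The ``anchors_k`` smallest-distance pairs become anchors; around each
    anchor, the ``window`` consecutive residues centred on the anchor
    residue in each chain (truncated at chain ends) form up to
    window x window candidate pairs.  Duplicates are removed keeping the
    first occurrence; the final order is anchors by ascending distance,
    within an anchor row-major (receptor index, then ligand index).

    When ``anchors_k`` is omitted and the pairs are labelled, it defaults to
    twice the number of positive pairs (enough anchors to retain every
    labelled positive whose distance ranks among the smallest, plus an equal
    number of negative anchors).
    """
    if window % 2 == 0 or window < 1:
        raise ConfigurationError(f"window must be odd and positive, got {window}")
    if anchors_k is None:
        n_pos = sum(1 for p in pairs if p.label == 1)
        if n_pos == 0:
            raise ConfigurationError(
                "anchors_k must be given explicitly for unlabeled or "
                "all-negative pair lists")
        anchors_k = 2 * n_pos
    if anchors_k < 1:
        raise ConfigurationError("anchors_k must be >= 1")

    by_key = {p.key: p for p in pairs}
    rec_indices = sorted({p.receptor.index for p in pairs})
    lig_indices = sorted({p.ligand.index for p in pairs})
    rec_pos = {idx: i for i, idx in enumerate(rec_indices)}
    lig_pos = {idx: i for i, idx in enumerate(lig_indices)}
    half = window // 2

    order = sorted(range(len(pairs)), key=lambda i: (pairs[i].distance, i))
    anchors = [pairs[i] for i in order[:anchors_k]]

    selected: dict[tuple[int, int], PairExample] = {}
    for anchor in anchors:
        rp, lp = rec_pos[anchor.receptor.index], lig_pos[anchor.ligand.index]
        r_window = rec_indices[max(0, rp - half): rp + half + 1]
        l_window = lig_indices[max(0, lp - half): lp + half + 1]
        for ri in r_window:
            for li in l_window:
                key = (ri, li)
                if key not in selected and key in by_key:
                    selected[key] = by_key[key]
    return DimerPairSet(dimer_id=dimer_id, pairs=list(selected.values()),
                        tnrp=len(pairs))


def assemble_matrix(dimer_pair_set: DimerPairSet) -> tuple[np.ndarray, np.ndarray]:
    """Stack the ordered pair features into an L x 18 matrix with the
    aligned length-L binary label vector."""
    pairs = dimer_pair_set.pairs
    widths = {len(p.features) for p in pairs}
    if widths != {2 * len(FEATURE_NAMES)}:
        raise ValidationError(f"ragged or mis-sized feature vectors: widths {widths}")
    X = np.vstack([p.features for p in pairs]).astype(float)
    y = np.array([0 if p.label is None else int(p.label) for p in pairs], dtype=int)
    return X, y


# ---------------------------------------------------------------------------
# Dataset split
# ---------------------------------------------------------------------------

def split_dimers(dimer_ids: Sequence[str], ratio: tuple = (6, 2, 2),
                 seed: int = 0) -> DatasetSplit:
    """Seeded random train/validation/test partition of dimer ids.

    Sizes follow largest-remainder apportionment of the ratio, so 54 dimers
    at 6:2:2 give 32/11/11.  Partitions are disjoint and exhaustive for any
    seed, and the split is deterministic under the seed.
    """
    ids = list(dimer_ids)
    if len(ratio) != 3 or any(r < 0 for r in ratio) or sum(ratio) <= 0:
        raise ConfigurationError(f"degenerate split ratio {ratio}")
    if len(ids) < 3:
        raise ValidationError("need at least 3 dimers to split")
    n = len(ids)
    total = sum(ratio)
    quotas = [n * r / total for r in ratio]
    sizes = [int(np.floor(q)) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    for i in sorted(range(3), key=lambda i: (-remainders[i], i))[: n - sum(sizes)]:
        sizes[i] += 1
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(n)]
    train = perm[:sizes[0]]
    validation = perm[sizes[0]:sizes[0] + sizes[1]]
    test = perm[sizes[0] + sizes[1]:]
    return DatasetSplit(train=train, validation=validation, test=test,
                        ratio=tuple(ratio), seed=seed)
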
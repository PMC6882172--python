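"""Synthetic dimers with the statistical structure the pipeline assumes.

Real inputs to the pipeline are per-residue feature tables computed from
monomer structures plus per-dimer contact areas.  This generator emulates
exactly that relational structure — and nothing more — so that every stage
(pairing, labelling, reduction, training, ranking) is testable without any
download:

* geometry: a two-blob layout.  A contiguous patch of residues in each
  chain sits inside a small contact region (all cross-patch representative-
  atom distances below ``d_contact``); every other residue lies far away
  (all other cross-chain distances well above ``d_contact``).  Physical
  realism is out of scope — only the distance/label relations matter.
* contact areas: exactly the residue pairs within ``d_contact`` get a
  positive area, so the generator and :func:`ppilstm.pairs.label_interface`
  agree by construction, and a patch of size k yields exactly k*k positive
  pairs out of len_receptor * len_ligand candidates (the extreme class
  imbalance of real dimers).
* features: Gaussian class-conditional.  Non-interface residues draw the 9
  features from baseline per-feature means and standard deviations loosely
  modelled on real surface-residue values (areas in A^2, RESA a ratio,
  hydropathy indices, pKa units); interface residues are shifted by
  ``effect_size`` pooled standard deviations.  ``effect_size=0`` makes the
  classes indistinguishable.

Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import pairs as P
from .exceptions import ConfigurationError
from .pairs import ResidueRecord

__all__ = ["SyntheticDimerSpec", "SyntheticDimer", "generate_dimer",
           "generate_dataset", "prepare_dimer"]

# Baseline per-feature means and standard deviations for the 9 features
# (IC, EC, EV, AESA, RESA, H1, H2, pKa1, pKa2).
_DEFAULT_MEANS = (35.0, 40.0, 10.0, 60.0, 0.40, -0.5, 0.10, 6.5, 6.0)
_DEFAULT_STDS = (10.0, 12.0, 5.0, 25.0, 0.15, 2.5, 0.50, 1.5, 1.2)


@dataclass(frozen=True)
class SyntheticDimerSpec:
    """Study conditions for one synthetic dimer."""

    len_receptor: int = 20
    len_ligand: int = 25
    patch_size: int = 3             # interface patch, patch_size residues per chain
    effect_size: float = 2.0        # interface feature shift, in pooled SDs
    d_contact: float = 8.0          # contact distance threshold (Angstrom)
    feature_means: tuple = _DEFAULT_MEANS
    feature_stds: tuple = _DEFAULT_STDS
    seed: int = 0

    def __post_init__(self):
        if self.patch_size > min(self.len_receptor, self.len_ligand):
            raise ConfigurationError(
                f"patch size {self.patch_size} exceeds a chain length")
        if self.patch_size < 1 or self.len_receptor < 1 or self.len_ligand < 1:
            raise ConfigurationError("chain and patch sizes must be positive")
        if self.effect_size < 0:
            raise ConfigurationError("effect size must be nonnegative")
        if len(self.feature_means) != 9 or len(self.feature_stds) != 9:
            raise ConfigurationError("need 9 feature means and 9 stds")

    @property
    def positive_fraction(self) -> float:
        """Target label imbalance: interface pairs over all candidate pairs."""
        return self.patch_size ** 2 / (self.len_receptor * self.len_ligand)


@dataclass
class SyntheticDimer:
    dimer_id: str
    chains: dict                    # chain id -> list[ResidueRecord]
    contact_areas: dict             # (receptor_index, ligand_index) -> area
    n_candidate_pairs: int          # N
    n_interface_pairs: int          # M


def _patch_start(length: int, patch: int) -> int:
    return (length - patch) // 2


def _make_chain(rng: np.random.Generator, chain_id: str, length: int,
                patch_start: int, patch: int, spec: SyntheticDimerSpec,
                contact_center: np.ndarray, away_direction: float) -> list:
    """Interface residues jitter inside a 1-Angstrom ball around the contact
    center; the rest march away along x at 3-Angstrom spacing starting 20
    Angstrom out, so every non-patch cross-chain distance exceeds
    d_contact by a wide margin."""
    means = np.asarray(spec.feature_means)
    stds = np.asarray(spec.feature_stds)
    records = []
    far_rank = 0
    for i in range(length):
        in_patch = patch_start <= i < patch_start + patch
        if in_patch:
            coord = contact_center + rng.uniform(-1.0, 1.0, size=3)
            feats = rng.normal(means + spec.effect_size * stds, stds)
        else:
            coord = np.array([away_direction * (20.0 + 3.0 * far_rank),
                              rng.uniform(-1.0, 1.0), rng.uniform(-1.0, 1.0)])
            far_rank += 1
            feats = rng.normal(means, stds)
        records.append(ResidueRecord(chain=chain_id, index=i + 1,
                                     coord=tuple(float(c) for c in coord),
                                     features=tuple(float(f) for f in feats)))
    return records


def generate_dimer(spec: SyntheticDimerSpec, dimer_id: str = "SYN0000",
                   seed: Optional[int] = None) -> SyntheticDimer:
    """Generate one dimer: per-chain residue records plus the contact-area
    table.  Exactly the patch x patch cross pairs lie within ``d_contact``
    and carry positive contact area."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rs = _patch_start(spec.len_receptor, spec.patch_size)
    ls = _patch_start(spec.len_ligand, spec.patch_size)
    receptor = _make_chain(rng, "R", spec.len_receptor, rs, spec.patch_size,
                           spec, contact_center=np.zeros(3), away_direction=-1.0)
    ligand = _make_chain(rng, "L", spec.len_ligand, ls, spec.patch_size,
                         spec, contact_center=np.array([4.0, 0.0, 0.0]),
                         away_direction=+1.0)
    areas = {}
    for r in receptor[rs:rs + spec.patch_size]:
        for l in ligand[ls:ls + spec.patch_size]:
            areas[(r.index, l.index)] = float(rng.uniform(5.0, 30.0))
    return SyntheticDimer(dimer_id=dimer_id,
                          chains={"R": receptor, "L": ligand},
                          contact_areas=areas,
                          n_candidate_pairs=spec.len_receptor * spec.len_ligand,
                          n_interface_pairs=len(areas))


def prepare_dimer(dimer: SyntheticDimer, anchors_k: Optional[int] = None,
                  window: int = 3) -> P.DimerPairSet:
    """Run the full pair pipeline on one synthetic dimer: cross pairs,
    interface labels, distance-based negative reduction."""
    cross = P.build_cross_pairs(dimer.chains["R"], dimer.chains["L"])
    labelled = P.label_interface(cross, dimer.contact_areas)
    return P.reduce_negatives(labelled, anchors_k=anchors_k, window=window,
                              dimer_id=dimer.dimer_id)


def generate_dataset(n_dimers: int, spec: SyntheticDimerSpec,
                     split_ratio: tuple = (6, 2, 2), seed: int = 0
                     ) -> tuple[list, P.DatasetSplit]:
    """Generate ``n_dimers`` independent dimers (per-dimer seeds spawned
    from the master seed) and a seeded dimer-level split."""
    if n_dimers < 3:
        raise ConfigurationError("need at least 3 dimers for a 3-way split")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_dimers) % (2 ** 31)
    dimers = [generate_dimer(spec, dimer_id=f"SYN{i:04d}", seed=int(s))
              for i, s in enumerate(child_seeds)]
    split = P.split_dimers([d.dimer_id for d in dimers], ratio=split_ratio,
                           seed=seed)
    return dimers, split
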
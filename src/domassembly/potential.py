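"""Atomic coordinate deviation (ACD) potential.

For every targeted ordered pair (i, j) and every backbone atom
k in S_atoms = {N, CA, C, CB} of residue j, the deviation is

    || A_i^{-1} x_{j,k}  -  A_(i,j) A_j^{-1} x_{j,k} ||_2

where A_i, A_j are the conformation's current local->ground frames and
A_(i,j) is the target transform (decoded prediction or oracle). The first
term is the atom as residue i actually sees it; the second is where the
atom would sit in i's frame if the pair satisfied the target. F_ACD is the
mean over all N_tot = 4 P cumulative terms, in Angstrom. Both (i, j) and
(j, i) count as separate terms.

pACD scores a conformation against a predicted map, tACD against the
oracle of a reference structure; the two names share this one kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .frames import affines_from_6d, structure_frames
from .interactions import (InteractionMap, decode_distributions,
                           oracle_targets_from_structure)
from .structure import (BackboneStructure, DomainLayout, ensure_cbeta,
                        CB_, N_, CA_, C_)

#: Atom slots of S_atoms in the coordinate array (N, CA, C, CB).
ACD_ATOM_SLOTS = (N_, CA_, C_, CB_)


@dataclass
class ACDContext:
    """Precompiled target transforms for fast repeated evaluation.

    ``pair_i``/``pair_j`` are row indices into the conformation the context
    will be evaluated against; ``R_t``/``t_t`` hold A_(i,j).
    """

    pair_i: np.ndarray
    pair_j: np.ndarray
    R_t: np.ndarray
    t_t: np.ndarray
    index_map: list[tuple[str, int]]
    clamp: float | None = None
    steric_weight: float = 0.0
    steric_cutoff: float = 3.6

    def __post_init__(self):
        if len(self.pair_i) == 0:
            raise DegenerateInputError("ACD context has no pair")
        if self.clamp is not None and self.clamp <= 0:
            raise ValidationError("clamp must be positive")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_i)

    @property
    def n_tot(self) -> int:
        return 4 * len(self.pair_i)


def build_acd_context(m: InteractionMap, clamp: float | None = None,
                      steric_weight: float = 0.0) -> ACDContext:
    """Compile a mode-dialect map (dist maps are arg-max decoded first)."""
    if m.dialect == "dist":
        m = decode_distributions(m)
    R_t, t_t = affines_from_6d(m.values)
    return ACDContext(m.pairs[:, 0].copy(), m.pairs[:, 1].copy(), R_t, t_t,
                      list(m.index_map), clamp=clamp,
                      steric_weight=steric_weight)


def _check_alignment(conf: BackboneStructure, ctx: ACDContext) -> None:
    if len(conf) < len(ctx.index_map):
        raise ValidationError(
            "conformation has fewer residues than the interaction map")
    needed = np.union1d(ctx.pair_i, ctx.pair_j)
    for g in needed[:1]:  # spot check; full check is O(n) strings
        chain, resnum = ctx.index_map[g]
        if (str(conf.chain_ids[g]), int(conf.res_nums[g])) != (chain, resnum):
            raise ValidationError(
                "conformation residue order does not match the map's "
                "global indexing")


def acd(conf: BackboneStructure, ctx: ACDContext) -> float:
    """F_ACD of a conformation under a context's targets (Angstrom)."""
    _check_alignment(conf, ctx)
    conf = ensure_cbeta(conf)
    coords = conf.coords
    if not np.all(np.isfinite(coords[:, list(ACD_ATOM_SLOTS), :])):
        raise ValidationError("missing S_atoms coordinates")
    R, t = structure_frames(conf)

    ii, jj = ctx.pair_i, ctx.pair_j
    x = coords[jj][:, list(ACD_ATOM_SLOTS), :]          # (P, 4, 3)
    # R^T @ p per point is p @ R; batched matmul over pairs
    seen = (x - t[ii][:, None, :]) @ R[ii]       # atom as frame i sees it
    local_j = (x - t[jj][:, None, :]) @ R[jj]
    # where the atom would sit in i's frame if the target transform held
    want = local_j @ ctx.R_t.transpose(0, 2, 1) + ctx.t_t[:, None, :]
    dev = np.linalg.norm(seen - want, axis=2)            # (P, 4)
    if ctx.clamp is not None:
        dev = np.minimum(dev, ctx.clamp)
    energy = float(dev.mean())

    if ctx.steric_weight > 0.0:
        # soft repulsion between inter-domain CA pairs closer than the cutoff
        ca = conf.ca
        d = np.linalg.norm(ca[ii] - ca[jj], axis=1)
        overlap = np.maximum(0.0, ctx.steric_cutoff - d)
        energy += ctx.steric_weight * float(np.mean(overlap ** 2))
    return energy


def pacd(conf: BackboneStructure, predicted_map: InteractionMap,
         clamp: float | None = None) -> float:
    """ACD against a predicted interaction map (decoded if binned)."""
    return acd(conf, build_acd_context(predicted_map, clamp=clamp))


def tacd(conf: BackboneStructure, reference: BackboneStructure,
         layout: DomainLayout, r_max: float = 40.0) -> float:
    """ACD against the true transforms read off a reference structure."""
    m = oracle_targets_from_structure(reference, layout, r_max=r_max)
    return acd(conf, build_acd_context(m))
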
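"""Model evaluation: Kabsch RMSD, TM-score and inter-domain distance error.

TM-score is length-normalized topological similarity in (0, 1]:

    TM = max over superpositions of (1/L_ref) sum_i 1 / (1 + (d_i/d0)^2),
    d0 = 1.24 (L_ref - 15)^(1/3) - 1.8   (clamped below at 0.5)

computed with the standard fragment-seeded iterative superposition search.
The search is a heuristic maximization, so scores can in principle fall
marginally below the true optimum; identity and rigid-motion invariance
are exact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .interactions import InteractionMap
from .structure import BackboneStructure, DomainLayout


@dataclass
class Superposition:
    """Optimal rigid superposition mapping set a onto set b:
    ``b ~ rotation @ a + translation``."""
    rotation: np.ndarray
    translation: np.ndarray
    n_atoms: int
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> Superposition:
    """Least-squares rigid superposition (SVD Kabsch, proper rotation
    enforced) of matched point sets ``a`` onto ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValidationError("point sets must both be (n, 3)")
    n = len(a)
    if n < 3:
        raise ValidationError("need at least 3 points")
    ca_, cb_ = a.mean(axis=0), b.mean(axis=0)
    A = a - ca_
    B = b - cb_
    H = A.T @ B
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb_ - R @ ca_
    rmsd = float(np.sqrt(np.mean(np.sum((A @ R.T - B) ** 2, axis=1))))
    return Superposition(R, t, n, rmsd)


def _common_ca(model: BackboneStructure, ref: BackboneStructure
               ) -> tuple[np.ndarray, np.ndarray]:
    """CA coordinates of residues shared by both structures, ref order."""
    m_index = model.residue_index()
    rows_m, rows_r = [], []
    for i, key in enumerate(zip(ref.chain_ids, (int(x) for x in
                                                ref.res_nums))):
        j = m_index.get((str(key[0]), key[1]))
        if j is not None:
            rows_r.append(i)
            rows_m.append(j)
    return model.ca[rows_m], ref.ca[rows_r]


def ca_rmsd(model: BackboneStructure, ref: BackboneStructure) -> float:
    """Kabsch RMSD over the shared CA atoms."""
    m, r = _common_ca(model, ref)
    return kabsch_rmsd(m, r).rmsd


def tm_d0(l_ref: int) -> float:
    if l_ref <= 15:
        raise ValidationError("TM-score d0 needs L_ref > 15")
    return max(1.24 * (l_ref - 15) ** (1.0 / 3.0) - 1.8, 0.5)


def tm_score(model: BackboneStructure, ref: BackboneStructure) -> float:
    """TM-score of ``model`` against ``ref``, normalized by the reference
    length, maximized over fragment-seeded iteratively refined
    superpositions."""
    xm, xr = _common_ca(model, ref)
    n = len(xm)
    l_ref = len(ref)
    if n < 15:
        raise ValidationError("need >= 15 common residues for TM-score")
    d0 = tm_d0(l_ref)

    def score_from(sup: Superposition) -> tuple[float, np.ndarray]:
        d = np.linalg.norm(sup.apply(xm) - xr, axis=1)
        return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref), d

    best = 0.0
    frag_lengths = sorted({n, max(n // 2, 4), max(n // 4, 4), 4},
                          reverse=True)
    for fl in frag_lengths:
        step = max(1, fl // 2)
        for start in range(0, n - fl + 1, step):
            sel = np.arange(start, start + fl)
            prev: np.ndarray | None = None
            for _ in range(30):
                sup = kabsch_rmsd(xm[sel], xr[sel])
                s, d = score_from(sup)
                best = max(best, s)
                nxt = None
                for cut in (d0, d0 + 1.0, d0 + 2.0, d0 + 4.0, np.inf):
                    cand = np.flatnonzero(d < cut)
                    if len(cand) >= 3:
                        nxt = cand
                        break
                if prev is not None and np.array_equal(nxt, prev):
                    break
                prev, sel = nxt, nxt
    return best


def inter_domain_distance_error(pred: InteractionMap,
                                ref: BackboneStructure,
                                layout: DomainLayout | None = None,
                                aggregate: str = "mean") -> float:
    """Error (A) between predicted and true inter-domain CA-CA distances,
    aggregated over all ordered pairs present in the map (pairs decoded to
    the no-interaction bin are already absent)."""
    if pred.dialect != "mode":
        raise ValidationError("decode the map before computing the error")
    if len(pred) == 0:
        raise DegenerateInputError("empty interaction map")
    index = ref.residue_index()
    try:
        rows_i = np.array([index[pred.index_map[i]] for i in pred.pairs[:, 0]])
        rows_j = np.array([index[pred.index_map[j]] for j in pred.pairs[:, 1]])
    except KeyError as exc:
        raise ValidationError(
            f"map references residue absent from reference: {exc}") from exc
    true_d = np.linalg.norm(ref.ca[rows_i] - ref.ca[rows_j], axis=1)
    err = np.abs(pred.values[:, 3] - true_d)
    if aggregate == "mean":
        return float(err.mean())
    if aggregate == "median":
        return float(np.median(err))
    raise ValidationError(f"unknown aggregate {aggregate!r}")


def evaluate_models(models: list[tuple[str, BackboneStructure]],
                    ref: BackboneStructure, out_path=None,
                    pred: InteractionMap | None = None,
                    layout: DomainLayout | None = None) -> list[dict]:
    """RMSD/TM-score (and optional distance error) table; optionally
    written as TSV."""
    rows = []
    for name, st in models:
        row = {"model": name,
               "rmsd": ca_rmsd(st, ref),
               "tm_score": tm_score(st, ref)}
        if pred is not None:
            row["inter_domain_distance_error"] = \
                inter_domain_distance_error(pred, ref, layout)
        rows.append(row)
    if out_path is not None:
        with open(out_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            header = list(rows[0].keys())
            w.writerow(header)
            for row in rows:
                w.writerow([row[h] if h == "model" else f"{row[h]:.4f}"
                            for h in header])
    return rows
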
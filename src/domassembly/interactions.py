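"""Inter-domain interaction maps.

An :class:`InteractionMap` stores, for ordered inter-domain residue pairs
(i, j), either an exact 6D target transform (``mode`` dialect) or six
categorical distributions over a :class:`BinScheme` (``dist`` dialect, the
shape a predictor network would emit). The structure-derived oracle
(:func:`oracle_targets_from_structure`) plays the role of a perfect
predictor: it reads the true transforms off a reference structure, which
makes the whole assembly engine testable without any learned model.

Residue pairs are keyed by global indices: 0-based positions in the
concatenation of chains in the layout's chain order. The mapping from global
index to (chain, residue number) travels with the map and its file format.

Angles are radians internally; the TSV format uses degrees and Angstrom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import (DegenerateInputError, InteractionFormatError,
                     ValidationError)
from .frames import sixd_from_frame_pairs, structure_frames
from .structure import BackboneStructure, DomainLayout

ELEMENTS = ("alpha", "beta", "gamma", "r", "theta", "phi")
#: Elements that live on a circle (wrapped Gaussians when blurring).
PERIODIC = frozenset({"alpha", "gamma", "phi"})

#: Default blur widths used to emulate a soft predictor: half a bin.
DEFAULT_BLUR = {"alpha": np.deg2rad(7.5), "beta": np.deg2rad(7.5),
                "gamma": np.deg2rad(7.5), "r": 0.5,
                "theta": np.deg2rad(7.5), "phi": np.deg2rad(7.5)}

FORMAT_VERSION = "domassembly-interactions v1"


@dataclass
class BinScheme:
    """Per-element bin edges (radians / Angstrom, strictly increasing).

    The distance element carries one extra overflow bin past its last edge
    meaning "no interaction"; pairs decoded there are dropped. Finite bins
    decode to their midpoints.
    """

    edges: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for el in ELEMENTS:
            if el not in self.edges:
                raise ValidationError(f"bin scheme missing element {el!r}")
            e = np.asarray(self.edges[el], dtype=float)
            if np.any(np.diff(e) <= 0):
                raise ValidationError(f"{el} edges not strictly increasing")
            self.edges[el] = e

    @classmethod
    def default(cls, r_max: float = 40.0) -> "BinScheme":
        """r over [2, r_max] A at 1 A plus the overflow bin; alpha/gamma/phi
        over [-180, 180) deg at 15 deg; beta over [-90, 90]; theta over
        [0, 180]."""
        deg = np.deg2rad
        return cls({
            "alpha": deg(np.arange(-180.0, 180.1, 15.0)),
            "beta": deg(np.arange(-90.0, 90.1, 15.0)),
            "gamma": deg(np.arange(-180.0, 180.1, 15.0)),
            "r": np.arange(2.0, float(r_max) + 0.5, 1.0),
            "theta": deg(np.arange(0.0, 180.1, 15.0)),
            "phi": deg(np.arange(-180.0, 180.1, 15.0)),
        })

    def n_bins(self, el: str) -> int:
        n = len(self.edges[el]) - 1
        return n + 1 if el == "r" else n  # overflow bin for r

    def overflow_bin(self) -> int:
        return len(self.edges["r"]) - 1

    def midpoints(self, el: str) -> np.ndarray:
        e = self.edges[el]
        return (e[:-1] + e[1:]) / 2.0

    def half_widths(self, el: str) -> np.ndarray:
        e = self.edges[el]
        return np.diff(e) / 2.0

    def bin_of(self, el: str, values: np.ndarray) -> np.ndarray:
        """Finite bin index of each value; raises if outside the domain
        (the r overflow is handled by the caller)."""
        e = self.edges[el]
        v = np.asarray(values, dtype=float)
        if el in PERIODIC:
            # wrap values landing exactly on the upper edge back to the start
            v = np.mod(v - e[0], e[-1] - e[0]) + e[0]
        idx = np.searchsorted(e, v, side="right") - 1
        idx = np.where(np.isclose(v, e[-1]) & (idx == len(e) - 1),
                       len(e) - 2, idx)
        if np.any((idx < 0) | (idx > len(e) - 2)):
            bad = v[(idx < 0) | (idx > len(e) - 2)][0]
            raise ValidationError(
                f"{el} value {bad:g} outside bin scheme domain "
                f"[{e[0]:g}, {e[-1]:g}]")
        return idx

    # -- header (de)serialization; angles stored in degrees for readability

    def to_header(self) -> str:
        doc = {}
        for el in ELEMENTS:
            e = self.edges[el]
            doc[el] = [round(float(x), 9) for x in
                       (np.rad2deg(e) if el != "r" else e)]
        return json.dumps(doc)

    @classmethod
    def from_header(cls, text: str) -> "BinScheme":
        doc = json.loads(text)
        edges = {}
        for el in ELEMENTS:
            e = np.asarray(doc[el], dtype=float)
            edges[el] = e if el == "r" else np.deg2rad(e)
        return cls(edges)


@dataclass
class InteractionMap:
    """Sparse per-pair 6D targets or binned distributions.

    Attributes
    ----------
    pairs
        ``(P, 2)`` global residue indices; all pairs are inter-domain and
        both orderings are present for oracle maps.
    dialect
        ``"mode"`` (point targets) or ``"dist"`` (distributions).
    values
        ``(P, 6)`` array in ELEMENTS order, mode dialect only.
    dist
        Element -> ``(P, n_bins)`` probabilities, dist dialect only.
    index_map
        Global index -> (chain id, residue number).
    """

    pairs: np.ndarray
    dialect: str
    index_map: list[tuple[str, int]]
    values: np.ndarray | None = None
    dist: dict[str, np.ndarray] | None = None
    scheme: BinScheme | None = None
    provenance: str = "oracle"

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if self.dialect not in ("mode", "dist"):
            raise ValidationError(f"unknown dialect {self.dialect!r}")
        if self.dialect == "mode":
            if self.values is None:
                raise ValidationError("mode dialect requires values")
            self.values = np.asarray(self.values, dtype=float)
            if self.values.shape != (len(self.pairs), 6):
                raise ValidationError("values shape mismatch")
        else:
            if self.dist is None or self.scheme is None:
                raise ValidationError("dist dialect requires dist and scheme")
            for el in ELEMENTS:
                p = np.asarray(self.dist[el], dtype=float)
                if p.shape != (len(self.pairs), self.scheme.n_bins(el)):
                    raise ValidationError(f"dist[{el}] shape mismatch")
                if np.any(p < -1e-12):
                    raise ValidationError(f"negative probability in {el}")
                s = p.sum(axis=1)
                if len(p) and np.any(np.abs(s - 1.0) > 1e-6):
                    raise ValidationError(
                        f"{el} distributions do not sum to 1")
                self.dist[el] = p

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_residues(self) -> list[tuple[tuple[str, int], tuple[str, int]]]:
        return [(self.index_map[i], self.index_map[j])
                for i, j in self.pairs]


# ---------------------------------------------------------------------------
# Oracle generation


def global_index_map(structure: BackboneStructure) -> list[tuple[str, int]]:
    return [(str(c), int(r))
            for c, r in zip(structure.chain_ids, structure.res_nums)]


def oracle_targets_from_structure(ref: BackboneStructure,
                                  layout: DomainLayout,
                                  r_max: float = 40.0) -> InteractionMap:
    """Exact 6D transforms for every ordered inter-domain pair whose CA-CA
    distance is within ``r_max`` — the "true interactions" read off a
    reference structure. Both (i, j) and (j, i) are emitted."""
    if r_max <= 0:
        raise DegenerateInputError("r_max must be positive")
    ref = layout.attach(ref) if ref.domain_labels is None else ref
    labels = ref.domain_labels
    ca = ref.ca
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2)
    inter = labels[:, None] != labels[None, :]
    mask = inter & (d <= r_max)
    np.fill_diagonal(mask, False)
    ii, jj = np.nonzero(mask)
    if len(ii) == 0:
        raise DegenerateInputError(
            "no inter-domain residue pair within r_max")
    R, t = structure_frames(ref)
    values = sixd_from_frame_pairs(R[ii], t[ii], R[jj], t[jj])
    return InteractionMap(np.column_stack([ii, jj]), "mode",
                          global_index_map(ref), values=values,
                          provenance="oracle")


# ---------------------------------------------------------------------------
# Discretization / decoding


def _blur_row(el: str, value: float, edges: np.ndarray, sd: float,
              n_bins: int, overflow: bool) -> np.ndarray:
    """Probability row for one element value under Gaussian blur."""
    row = np.zeros(n_bins)
    lo, hi = edges[0], edges[-1]
    if el in PERIODIC:
        span = hi - lo
        for k in (-1.0, 0.0, 1.0):  # wrapped Gaussian images
            c = norm.cdf(edges, loc=value + k * span, scale=sd)
            row[:len(edges) - 1] += np.diff(c)
    else:
        c = norm.cdf(edges, loc=value, scale=sd)
        row[:len(edges) - 1] = np.diff(c)
        below = c[0]
        above = 1.0 - c[-1]
        if overflow:
            row[0] += below
            row[-1] += above  # mass past r_max -> no-interaction bin
        else:  # bounded elements: clamp tails into the end bins
            row[0] += below
            row[len(edges) - 2] += above
    s = row.sum()
    if s <= 0:
        raise ValidationError(f"{el} blur produced an empty distribution")
    return row / s


def discretize_targets(m: InteractionMap, scheme: BinScheme,
                       blur_sd: dict[str, float] | float | None = 0.0
                       ) -> InteractionMap:
    """Turn point targets into binned distributions.

    ``blur_sd`` gives per-element Gaussian widths (radians / Angstrom);
    zero (or None) produces delta distributions on the containing bin.
    Distance mass beyond the last r edge goes to the overflow bin.
    """
    if m.dialect != "mode":
        raise ValidationError("discretize_targets expects a mode-dialect map")
    if blur_sd is None:
        blur_sd = 0.0
    if np.isscalar(blur_sd):
        blur_sd = {el: float(blur_sd) for el in ELEMENTS}
    P = len(m)
    dist: dict[str, np.ndarray] = {}
    for col, el in enumerate(ELEMENTS):
        vals = m.values[:, col]
        nb = scheme.n_bins(el)
        rows = np.zeros((P, nb))
        sd = float(blur_sd.get(el, 0.0))
        if sd == 0.0:
            if el == "r":
                over = vals > scheme.edges["r"][-1]
                if np.any(~over):
                    rows[~over, scheme.bin_of(el, vals[~over])] = 1.0
                rows[over, scheme.overflow_bin()] = 1.0
            else:
                rows[np.arange(P), scheme.bin_of(el, vals)] = 1.0
        else:
            edges = scheme.edges[el]
            for p in range(P):
                rows[p] = _blur_row(el, vals[p], edges, sd, nb, el == "r")
        dist[el] = rows
    return InteractionMap(m.pairs.copy(), "dist", list(m.index_map),
                          dist=dist, scheme=scheme, provenance=m.provenance)


def decode_distributions(m: InteractionMap,
                         scheme: BinScheme | None = None) -> InteractionMap:
    """Arg-max decoding: each element becomes the midpoint of its most
    probable bin (ties -> lowest index). Pairs whose distance arg-max is the
    overflow bin are dropped ("no interaction")."""
    if m.dialect != "dist":
        raise ValidationError("decode_distributions expects a dist map")
    scheme = scheme or m.scheme
    keep = np.ones(len(m), dtype=bool)
    cols = {}
    for el in ELEMENTS:
        p = m.dist[el]
        if np.any(p < -1e-12):
            raise ValidationError(f"negative probability mass in {el}")
        best = np.argmax(p, axis=1)  # numpy argmax takes the lowest index
        if el == "r":
            keep &= best != scheme.overflow_bin()
        cols[el] = best
    mids = {el: scheme.midpoints(el) for el in ELEMENTS}
    values = np.column_stack([
        np.where(keep, mids[el][np.minimum(cols[el], len(mids[el]) - 1)], 0.0)
        for el in ELEMENTS])
    return InteractionMap(m.pairs[keep], "mode", list(m.index_map),
                          values=values[keep], provenance=m.provenance)


def acd_quantization_bound(true_map: InteractionMap, scheme: BinScheme,
                           local_radius: float = 3.0,
                           width_multiplier: float = 1.0) -> float:
    """Upper bound on the ACD a decoded map can assign to its own reference.

    Each decoded element sits within ``width_multiplier`` half-bin-widths of
    the truth, so per pair the target transform moves an atom at local
    radius ``y`` by at most ``(|da|+|db|+|dg|) y + dr + (r + dr)(dt + dp)``
    (unitary-factor telescoping for the rotation, a radial-then-angular path
    for the spherical translation). The mean of this bound over pairs bounds
    the energy difference.
    """
    if true_map.dialect != "mode":
        raise ValidationError("bound needs the true mode-dialect map")
    hw = {el: float(np.max(scheme.half_widths(el))) * width_multiplier
          for el in ELEMENTS}
    r = true_map.values[:, 3]
    per_pair = ((hw["alpha"] + hw["beta"] + hw["gamma"]) * local_radius
                + hw["r"] + (r + hw["r"]) * (hw["theta"] + hw["phi"]))
    return float(np.mean(per_pair))


# ---------------------------------------------------------------------------
# File I/O (UTF-8 TSV with '#' headers)


def write_interactions(m: InteractionMap, path) -> None:
    scheme = m.scheme if m.scheme is not None else None
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {FORMAT_VERSION}\n")
        fh.write(f"# dialect: {m.dialect}\n")
        if scheme is not None:
            fh.write(f"# scheme: {scheme.to_header()}\n")
        fh.write("# index_map: "
                 + json.dumps([[c, r] for c, r in m.index_map]) + "\n")
        fh.write(f"# provenance: {m.provenance}\n")
        if m.dialect == "mode":
            fh.write("# columns: i\tj\talpha\tbeta\tgamma\tr\ttheta\tphi\n")
            deg = np.rad2deg
            for (i, j), v in zip(m.pairs, m.values):
                fh.write(f"{i}\t{j}\t{deg(v[0]):.9g}\t{deg(v[1]):.9g}\t"
                         f"{deg(v[2]):.9g}\t{v[3]:.9g}\t{deg(v[4]):.9g}\t"
                         f"{deg(v[5]):.9g}\n")
        else:
            fh.write("# columns: i\tj\telement\tbin_index\tprobability\n")
            for p, (i, j) in enumerate(m.pairs):
                for el in ELEMENTS:
                    row = m.dist[el][p]
                    for b in np.flatnonzero(row > 0):
                        fh.write(f"{i}\t{j}\t{el}\t{b}\t{row[b]:.9g}\n")


def read_interactions(path) -> InteractionMap:
    dialect = None
    scheme = None
    index_map: list[tuple[str, int]] | None = None
    provenance = "external"
    pairs: list[tuple[int, int]] = []
    mode_rows: list[list[float]] = []
    dist_rows: dict[tuple[int, int], dict[str, dict[int, float]]] = {}

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                try:
                    if body.startswith("dialect:"):
                        dialect = body.split(":", 1)[1].strip()
                    elif body.startswith("scheme:"):
                        scheme = BinScheme.from_header(
                            body.split(":", 1)[1].strip())
                    elif body.startswith("index_map:"):
                        index_map = [(str(c), int(r)) for c, r in
                                     json.loads(body.split(":", 1)[1])]
                    elif body.startswith("provenance:"):
                        provenance = body.split(":", 1)[1].strip()
                except (ValueError, KeyError,
                        json.JSONDecodeError) as exc:
                    raise InteractionFormatError(str(exc), lineno) from exc
                continue
            if dialect not in ("mode", "dist"):
                raise InteractionFormatError(
                    "data row before a valid '# dialect:' header", lineno)
            fields = line.split("\t")
            try:
                if dialect == "mode":
                    if len(fields) != 8:
                        raise ValueError(f"expected 8 fields, got {len(fields)}")
                    i, j = int(fields[0]), int(fields[1])
                    a, b, g, r, t, p = (float(x) for x in fields[2:])
                    pairs.append((i, j))
                    mode_rows.append([np.deg2rad(a), np.deg2rad(b),
                                      np.deg2rad(g), r, np.deg2rad(t),
                                      np.deg2rad(p)])
                else:
                    if len(fields) != 5:
                        raise ValueError(f"expected 5 fields, got {len(fields)}")
                    i, j = int(fields[0]), int(fields[1])
                    el, b, prob = fields[2], int(fields[3]), float(fields[4])
                    if el not in ELEMENTS:
                        raise ValueError(f"unknown element {el!r}")
                    dist_rows.setdefault((i, j), {}).setdefault(
                        el, {})[b] = prob
            except ValueError as exc:
                raise InteractionFormatError(str(exc), lineno) from exc

    if index_map is None:
        raise InteractionFormatError("missing '# index_map:' header")
    if dialect == "mode":
        return InteractionMap(
            np.array(pairs, dtype=int).reshape(-1, 2), "mode", index_map,
            values=np.array(mode_rows, dtype=float).reshape(-1, 6),
            scheme=scheme, provenance=provenance)
    if scheme is None:
        raise InteractionFormatError("dist dialect requires a scheme header")
    keys = list(dist_rows)
    dist = {el: np.zeros((len(keys), scheme.n_bins(el))) for el in ELEMENTS}
    for p, key in enumerate(keys):
        for el in ELEMENTS:
            for b, prob in dist_rows[key].get(el, {}).items():
                if not 0 <= b < scheme.n_bins(el):
                    raise InteractionFormatError(
                        f"bin index {b} out of range for {el}")
                dist[el][p, b] = prob
    return InteractionMap(np.array(keys, dtype=int).reshape(-1, 2), "dist",
                          index_map, dist=dist, scheme=scheme,
                          provenance=provenance)
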
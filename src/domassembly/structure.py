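"""Backbone structures, domain layouts and PDB I/O.

The in-memory representation is deliberately small: a structure is an ordered
table of residues, each carrying up to five heavy atoms (N, CA, C, O, CB) as
Cartesian coordinates in Angstrom. Missing atoms are NaN. Domains are rigid
bodies defined by a :class:`DomainLayout`, an explicit input (this package
does not predict domain boundaries).

PDB parsing and writing are delegated to :mod:`gemmi`; only backbone
extraction, validation and layout bookkeeping live here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import GeometryError, LayoutError, PDBFormatError, ValidationError

log = logging.getLogger(__name__)

#: Atom slot order of the coordinate array.
ATOM_ORDER = ("N", "CA", "C", "O", "CB")
N_, CA_, C_, O_, CB_ = range(5)

#: Standard amino acids retained by the parser.
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Ideal virtual C-beta geometry: bond length from CA and the (equal) angles
# it makes with the CA->N and CA->C directions.
CB_BOND_LENGTH = 1.522
CB_ANGLE_DEG = 110.4


@dataclass
class BackboneStructure:
    """Ordered backbone residues of one or more chains.

    Attributes
    ----------
    chain_ids, res_nums, res_names
        Per-residue chain identifier, residue number and 3-letter code.
    coords
        ``(n, 5, 3)`` array in the :data:`ATOM_ORDER` slot order; NaN marks
        an absent atom (typically O or CB in experimental files).
    domain_labels
        Optional per-residue domain identifier attached from a layout.
    """

    chain_ids: np.ndarray
    res_nums: np.ndarray
    res_names: np.ndarray
    coords: np.ndarray
    domain_labels: np.ndarray | None = None

    def __post_init__(self):
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.res_nums = np.asarray(self.res_nums, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.chain_ids)
        if self.coords.shape != (n, 5, 3):
            raise ValidationError(
                f"coords shape {self.coords.shape} != ({n}, 5, 3)")
        if self.domain_labels is not None:
            self.domain_labels = np.asarray(self.domain_labels, dtype=object)
            if len(self.domain_labels) != n:
                raise ValidationError("domain_labels length mismatch")

    def __len__(self) -> int:
        return len(self.chain_ids)

    @property
    def n_residues(self) -> int:
        return len(self.chain_ids)

    def copy(self) -> "BackboneStructure":
        return BackboneStructure(
            self.chain_ids.copy(), self.res_nums.copy(),
            self.res_names.copy(), self.coords.copy(),
            None if self.domain_labels is None else self.domain_labels.copy())

    def atoms(self, name: str) -> np.ndarray:
        """Coordinates of one backbone atom for every residue, ``(n, 3)``."""
        return self.coords[:, ATOM_ORDER.index(name), :]

    @property
    def ca(self) -> np.ndarray:
        return self.coords[:, CA_, :]

    def subset(self, index) -> "BackboneStructure":
        """Row-subset preserving order (used to cut out single domains)."""
        index = np.asarray(index)
        return BackboneStructure(
            self.chain_ids[index], self.res_nums[index],
            self.res_names[index], self.coords[index],
            None if self.domain_labels is None else self.domain_labels[index])

    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c, None)
        return list(seen)

    def chain_slice(self, chain: str) -> np.ndarray:
        return np.flatnonzero(self.chain_ids == chain)

    def residue_index(self) -> dict[tuple[str, int], int]:
        """Map (chain id, residue number) -> row index."""
        return {(c, int(r)): i
                for i, (c, r) in enumerate(zip(self.chain_ids, self.res_nums))}

    def validate(self, strict: bool = False) -> list[str]:
        """Check ordering and backbone bond lengths.

        Returns the list of complaints; raises only for hard violations
        (non-increasing residue numbers) or, with ``strict``, for any.
        """
        issues: list[str] = []
        for chain in self.chains():
            rows = self.chain_slice(chain)
            nums = self.res_nums[rows]
            if np.any(np.diff(nums) <= 0):
                raise ValidationError(
                    f"residue numbers not strictly increasing in chain {chain}")
        if not np.all(np.isfinite(self.coords[:, (N_, CA_, C_), :])):
            raise ValidationError("non-finite N/CA/C coordinates")
        n_ca = np.linalg.norm(self.coords[:, CA_] - self.coords[:, N_], axis=1)
        ca_c = np.linalg.norm(self.coords[:, C_] - self.coords[:, CA_], axis=1)
        for name, d in (("N-CA", n_ca), ("CA-C", ca_c)):
            bad = np.flatnonzero((d <= 1.2) | (d >= 1.8))
            for i in bad:
                issues.append(
                    f"{name} bond of {self.chain_ids[i]}{self.res_nums[i]} "
                    f"is {d[i]:.3f} A (expected within (1.2, 1.8))")
        if issues:
            if strict:
                raise ValidationError("; ".join(issues))
            for msg in issues:
                log.warning("%s", msg)
        return issues


# ---------------------------------------------------------------------------
# Domain layout


@dataclass
class Domain:
    id: str
    chain: str
    ranges: list[tuple[int, int]]

    def __post_init__(self):
        self.ranges = [(int(a), int(b)) for a, b in self.ranges]
        for a, b in self.ranges:
            if a > b:
                raise LayoutError(f"domain {self.id}: range [{a},{b}] reversed")

    def contains(self, resnum: int) -> bool:
        return any(a <= resnum <= b for a, b in self.ranges)

    def residue_numbers(self) -> list[int]:
        out: list[int] = []
        for a, b in self.ranges:
            out.extend(range(a, b + 1))
        return out


@dataclass
class DomainLayout:
    """Partition of one or more chains into domains.

    ``chains`` fixes the chain order used for the global residue indexing of
    interaction maps; ``domains`` lists non-overlapping residue-number ranges
    which together must cover every residue of the structure they label.
    """

    chains: list[str]
    domains: list[Domain] = field(default_factory=list)

    def __post_init__(self):
        if not self.domains:
            raise LayoutError("layout needs at least one domain")
        ids = [d.id for d in self.domains]
        if len(set(ids)) != len(ids):
            raise LayoutError("duplicate domain ids")
        for d in self.domains:
            if d.chain not in self.chains:
                raise LayoutError(
                    f"domain {d.id} references unknown chain {d.chain!r}")
        # overlap check within each chain
        for chain in self.chains:
            spans = []
            for d in self.domains:
                if d.chain == chain:
                    spans.extend((a, b, d.id) for a, b in d.ranges)
            spans.sort()
            for (a1, b1, i1), (a2, b2, i2) in zip(spans, spans[1:]):
                if a2 <= b1:
                    raise LayoutError(
                        f"domains {i1} and {i2} overlap on chain {chain}")

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_json(cls, text: str) -> "DomainLayout":
        try:
            doc = json.loads(text)
            domains = [Domain(d["id"], d["chain"],
                              [tuple(r) for r in d["ranges"]])
                       for d in doc["domains"]]
            return cls(list(doc["chains"]), domains)
        except (KeyError, TypeError, json.JSONDecodeError) as exc:
            raise LayoutError(f"malformed layout document: {exc}") from exc

    def to_json(self) -> str:
        doc = {
            "chains": list(self.chains),
            "domains": [{"id": d.id, "chain": d.chain,
                         "ranges": [list(r) for r in d.ranges]}
                        for d in self.domains],
        }
        return json.dumps(doc, indent=2) + "\n"

    @classmethod
    def from_file(cls, path) -> "DomainLayout":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(fh.read())

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    # -- structure bookkeeping ----------------------------------------------

    def domain_of(self, chain: str, resnum: int) -> str | None:
        for d in self.domains:
            if d.chain == chain and d.contains(resnum):
                return d.id
        return None

    def domains_in_chain(self, chain: str) -> list[Domain]:
        """Domains of one chain, ordered along the sequence."""
        ds = [d for d in self.domains if d.chain == chain]
        ds.sort(key=lambda d: min(a for a, _ in d.ranges))
        return ds

    def assign_labels(self, structure: BackboneStructure) -> np.ndarray:
        """Per-residue domain ids; raises if any residue is uncovered or the
        layout references residues absent from the structure."""
        labels = np.empty(len(structure), dtype=object)
        for i, (c, r) in enumerate(zip(structure.chain_ids,
                                       structure.res_nums)):
            d = self.domain_of(c, int(r))
            if d is None:
                raise LayoutError(
                    f"residue {c}{r} is not covered by any domain")
            labels[i] = d
        present = set(zip(structure.chain_ids,
                          (int(r) for r in structure.res_nums)))
        for d in self.domains:
            for rn in d.residue_numbers():
                if (d.chain, rn) not in present:
                    raise LayoutError(
                        f"domain {d.id} references absent residue "
                        f"{d.chain}{rn}")
        return labels

    def attach(self, structure: BackboneStructure) -> BackboneStructure:
        """Return the structure reordered to this layout's chain order with
        domain labels attached."""
        order: list[int] = []
        for chain in self.chains:
            rows = structure.chain_slice(chain)
            if rows.size == 0:
                raise LayoutError(f"structure has no chain {chain!r}")
            order.extend(rows.tolist())
        if len(order) != len(structure):
            extra = [c for c in structure.chains() if c not in self.chains]
            raise LayoutError(f"structure chains {extra} missing from layout")
        out = structure.subset(order)
        out.domain_labels = self.assign_labels(out)
        return out

    def boundaries(self) -> list[tuple[str, str, str, int]]:
        """Junctions between sequence-adjacent domains of the same chain.

        Returns ``(chain, upstream domain id, downstream domain id,
        junction residue number)`` where the junction residue is the last
        residue of the upstream domain.
        """
        out = []
        for chain in self.chains:
            ds = self.domains_in_chain(chain)
            for up, down in zip(ds, ds[1:]):
                out.append((chain, up.id, down.id,
                            max(b for _, b in up.ranges)))
        return out


# ---------------------------------------------------------------------------
# Virtual C-beta


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal C-beta position from the backbone N, CA, C atoms.

    The CB is placed 1.522 A from CA making equal 110.4 deg angles with the
    CA->N and CA->C bonds, on the side consistent with L-amino-acid
    chirality. Deterministic and rigid-motion equivariant. Accepts single
    points or ``(n, 3)`` stacks.
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    single = n.ndim == 1
    n, ca, c = np.atleast_2d(n), np.atleast_2d(ca), np.atleast_2d(c)

    u = n - ca
    v = c - ca
    nu = np.linalg.norm(u, axis=1, keepdims=True)
    nv = np.linalg.norm(v, axis=1, keepdims=True)
    if np.any(nu < 1e-9) or np.any(nv < 1e-9):
        raise GeometryError("coincident atoms in virtual_cbeta input")
    u = u / nu
    v = v / nv
    w = np.cross(u, v)
    nw = np.linalg.norm(w, axis=1, keepdims=True)
    if np.any(nw < 1e-6):
        raise GeometryError("collinear N/CA/C in virtual_cbeta input")
    e3 = w / nw
    bis = u + v
    e1 = bis / np.linalg.norm(bis, axis=1, keepdims=True)
    # direction makes angle CB_ANGLE with both u and v:
    # dir . u = p * (u . e1) with u.e1 = cos(half angle between u and v)
    cos_half = np.sqrt(np.clip((1.0 + np.sum(u * v, axis=1)) / 2.0,
                               1e-12, None))
    # For grossly distorted triples (N-CA-C wider than ~139 deg) the
    # equal-angle placement has no out-of-plane solution; degrade smoothly
    # to the in-plane anti-bisector while keeping the exact bond length.
    p = np.clip(np.cos(np.deg2rad(CB_ANGLE_DEG)) / cos_half, -1.0, 1.0)
    q = np.sqrt(1.0 - p ** 2)
    direction = p[:, None] * e1 + q[:, None] * e3
    cb = ca + CB_BOND_LENGTH * direction
    return cb[0] if single else cb


def ensure_cbeta(structure: BackboneStructure) -> BackboneStructure:
    """Fill missing CB slots (glycine, sparse files) with the virtual CB.

    Every residue gets a CB so the ACD atom set {N, CA, C, CB} is uniform;
    glycine is never special-cased. Operates in place and returns the input.
    """
    missing = ~np.all(np.isfinite(structure.coords[:, CB_, :]), axis=1)
    if np.any(missing):
        structure.coords[missing, CB_, :] = virtual_cbeta(
            structure.coords[missing, N_],
            structure.coords[missing, CA_],
            structure.coords[missing, C_])
    return structure


# ---------------------------------------------------------------------------
# PDB I/O


def read_pdb(path, layout: DomainLayout | None = None) -> BackboneStructure:
    """Read backbone atoms of the first model of a PDB file.

    Only standard amino acids with altloc blank or 'A' are kept; residues
    missing any of N/CA/C are dropped with a warning. When a layout is given
    the residues are reordered to its chain order and labelled by domain.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise PDBFormatError(f"{path}: no model")
    st.setup_entities()
    model = st[0]

    chain_ids, res_nums, res_names, coords = [], [], [], []
    for chain in model:
        for res in chain:
            if res.name not in STANDARD_AA:
                continue
            slots = np.full((5, 3), np.nan)
            for atom in res:
                if atom.altloc not in ("", "\0", "A"):  # gemmi: '\0' = none
                    continue
                if atom.name in ATOM_ORDER:
                    slots[ATOM_ORDER.index(atom.name)] = (
                        atom.pos.x, atom.pos.y, atom.pos.z)
            if not np.all(np.isfinite(slots[(N_, CA_, C_), :])):
                log.warning("dropping %s %s%d: incomplete backbone",
                            res.name, chain.name, res.seqid.num)
                continue
            chain_ids.append(chain.name)
            res_nums.append(res.seqid.num)
            res_names.append(res.name)
            coords.append(slots)
    if not coords:
        raise PDBFormatError(f"{path}: no parsable backbone residue")
    structure = BackboneStructure(
        np.array(chain_ids, dtype=object), np.array(res_nums),
        np.array(res_names, dtype=object), np.stack(coords))
    structure.validate()
    if layout is not None:
        structure = layout.attach(structure)
    return structure


def write_pdb(structure: BackboneStructure, path) -> None:
    """Write standard ATOM records (8.3 coordinates), TER between chains."""
    if len(structure) == 0:
        raise ValidationError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = "domassembly"
    model = gemmi.Model("1")
    for chain_name in structure.chains():
        chain = gemmi.Chain(chain_name)
        for i in structure.chain_slice(chain_name):
            res = gemmi.Residue()
            res.name = str(structure.res_names[i])
            res.seqid = gemmi.SeqId(int(structure.res_nums[i]), " ")
            res.het_flag = "A"  # always ATOM records, even 1-residue chains
            for k, name in enumerate(ATOM_ORDER):
                xyz = structure.coords[i, k]
                if not np.all(np.isfinite(xyz)):
                    continue
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(name[:1])
                atom.pos = gemmi.Position(*xyz)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def extract_domains(structure: BackboneStructure,
                    layout: DomainLayout) -> list[BackboneStructure]:
    """Cut a labelled full-length structure into one structure per domain,
    in layout order (the natural input for assembly)."""
    if structure.domain_labels is None:
        structure = layout.attach(structure)
    return [structure.subset(structure.domain_labels == d.id)
            for d in layout.domains]
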
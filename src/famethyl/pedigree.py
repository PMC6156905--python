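"""Pedigrees and kinship coefficient matrices.

A :class:`Pedigree` is a validated collection of individuals grouped into
families, with optional father/mother links.  :func:`compute_kinship` turns a
pedigree into the matrix of kinship coefficients Phi by the standard tabular
recursion (self-kinship 0.5 for a non-inbred individual).  Model code that
needs the additive (numerator) relationship matrix should use
``KinshipMatrix.relationship()``, i.e. 2*Phi.

PED input/output follows the PLINK pedigree dialect: whitespace-delimited
``FID IID PAT MAT SEX`` with ``0`` for a missing parent and sex coded
1=male, 2=female.  Columns beyond SEX are ignored on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MALE = "male"
FEMALE = "female"

_SEX_FROM_CODE = {"1": MALE, "2": FEMALE}
_CODE_FROM_SEX = {MALE: "1", FEMALE: "2"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (bad parent link, cycle, duplicate id)."""


class PedParseError(PedigreeError):
    """Malformed PED input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class Individual:
    iid: str
    fid: str
    father: str | None = None
    mother: str | None = None
    sex: str = MALE

    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """Validated family graph.

    Invariants enforced at construction: unique individual ids; each parent
    reference points to an existing member of the same family with the
    appropriate sex; the parent relation is acyclic.
    """

    individuals: list[Individual]
    _by_iid: dict[str, Individual] = field(init=False, repr=False)
    _topo: list[Individual] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_iid = {}
        for ind in self.individuals:
            if ind.iid in self._by_iid:
                raise PedigreeError(f"duplicate individual id {ind.iid!r}")
            if ind.sex not in (MALE, FEMALE):
                raise PedigreeError(f"unknown sex {ind.sex!r} for {ind.iid!r}")
            self._by_iid[ind.iid] = ind
        for ind in self.individuals:
            for role, pid, want in (
                ("father", ind.father, MALE),
                ("mother", ind.mother, FEMALE),
            ):
                if pid is None:
                    continue
                parent = self._by_iid.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.iid!r} is not in the pedigree"
                    )
                if parent.fid != ind.fid:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.iid!r} belongs to a different family"
                    )
                if parent.sex != want:
                    raise PedigreeError(
                        f"{role} {pid!r} of {ind.iid!r} has sex {parent.sex}"
                    )
        self._topo = self._topological_order()

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, iid: str) -> Individual:
        return self._by_iid[iid]

    def _topological_order(self) -> list[Individual]:
        # Kahn's algorithm on parent->child edges; leftover nodes mean a cycle.
        indeg = {ind.iid: 0 for ind in self.individuals}
        children: dict[str, list[str]] = {ind.iid: [] for ind in self.individuals}
        for ind in self.individuals:
            for pid in (ind.father, ind.mother):
                if pid is not None:
                    indeg[ind.iid] += 1
                    children[pid].append(ind.iid)
        queue = [ind.iid for ind in self.individuals if indeg[ind.iid] == 0]
        order: list[Individual] = []
        while queue:
            iid = queue.pop()
            order.append(self._by_iid[iid])
            for child in children[iid]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
        if len(order) != len(self.individuals):
            raise PedigreeError("cycle detected in parent relation")
        return order

    def topological_order(self) -> list[Individual]:
        """Members with every parent preceding its children."""
        return list(self._topo)

    def families(self) -> dict[str, list[Individual]]:
        """Family id -> members, families in order of first appearance."""
        fams: dict[str, list[Individual]] = {}
        for ind in self.individuals:
            fams.setdefault(ind.fid, []).append(ind)
        return fams


@dataclass
class KinshipMatrix:
    """Kinship coefficients Phi for an ordered set of individuals.

    ``ids`` are ordered family-block-contiguously so that per-family blocks
    are contiguous slices; ``family_ids`` is aligned with ``ids``.
    """

    ids: list[str]
    phi: np.ndarray
    family_ids: list[str]

    def relationship(self) -> np.ndarray:
        """Additive relationship matrix 2*Phi (unit diagonal for non-inbred)."""
        return 2.0 * self.phi

    def index_of(self, iid: str) -> int:
        return self.ids.index(iid)

    def family_slices(self) -> dict[str, slice]:
        fams: dict[str, list[int]] = {}
        for i, fid in enumerate(self.family_ids):
            fams.setdefault(fid, []).append(i)
        out: dict[str, slice] = {}
        for fid, idx in fams.items():
            lo, hi = idx[0], idx[-1] + 1
            if idx != list(range(lo, hi)):
                raise PedigreeError(f"family {fid!r} block is not contiguous")
            out[fid] = slice(lo, hi)
        return out


def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Kinship matrix by the tabular recursion, one family block at a time.

    Founders: phi(i,i)=0.5, phi(i,j)=0 for distinct founders.  A non-founder
    ``i`` with parents ``f, m``: phi(i,j) = (phi(f,j)+phi(m,j))/2 for j != i
    already placed, and phi(i,i) = (1 + phi(f,m))/2.  Individuals from
    different families have kinship 0, so the matrix is block diagonal.
    """
    topo_rank = {ind.iid: k for k, ind in enumerate(ped.topological_order())}
    ids: list[str] = []
    family_ids: list[str] = []
    blocks: list[np.ndarray] = []
    for fid, members in ped.families().items():
        members = sorted(members, key=lambda ind: topo_rank[ind.iid])
        n = len(members)
        pos = {ind.iid: k for k, ind in enumerate(members)}
        phi = np.zeros((n, n))
        for k, ind in enumerate(members):
            if ind.is_founder():
                phi[k, k] = 0.5
                continue
            fa, mo = pos[ind.father], pos[ind.mother]
            for j in range(k):
                phi[k, j] = phi[j, k] = 0.5 * (phi[fa, j] + phi[mo, j])
            phi[k, k] = 0.5 * (1.0 + phi[fa, mo])
        ids.extend(ind.iid for ind in members)
        family_ids.extend(fid for _ in members)
        blocks.append(phi)
    n = len(ids)
    full = np.zeros((n, n))
    start = 0
    for block in blocks:
        stop = start + block.shape[0]
        full[start:stop, start:stop] = block
        start = stop
    return KinshipMatrix(ids=ids, phi=full, family_ids=family_ids)


def read_ped(path) -> Pedigree:
    """Read a PLINK-dialect PED file (5 leading columns used)."""
    individuals: list[Individual] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise PedParseError(
                    f"expected at least 5 columns, found {len(fields)}", lineno
                )
            fid, iid, pat, mat, sexcode = fields[:5]
            sex = _SEX_FROM_CODE.get(sexcode)
            if sex is None:
                raise PedParseError(f"unknown sex code {sexcode!r}", lineno)
            if any(ind.iid == iid for ind in individuals):
                raise PedParseError(f"duplicate individual id {iid!r}", lineno)
            individuals.append(
                Individual(
                    iid=iid,
                    fid=fid,
                    father=None if pat == "0" else pat,
                    mother=None if mat == "0" else mat,
                    sex=sex,
                )
            )
    return Pedigree(individuals)


def write_ped(ped: Pedigree, path) -> None:
    """Write the 5-column PED representation (missing parents coded 0)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for ind in ped.individuals:
            fh.write(
                " ".join(
                    [
                        ind.fid,
                        ind.iid,
                        ind.father or "0",
                        ind.mother or "0",
                        _CODE_FROM_SEX[ind.sex],
                    ]
                )
                + "\n"
            )
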
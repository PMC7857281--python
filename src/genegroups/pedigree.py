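"""Pedigree handling for genetic-groups quantitative genetics.

Reads, validates, prunes and annotates pedigrees, and computes the
pedigree-derived quantities every downstream analysis consumes:

* per-individual expected immigrant genetic-group coefficients ``q``
  (the expected fraction of the genome derived from immigrant founders),
* Wright's inbreeding coefficients ``f`` (kinship of the parents),
* the sparse inverse additive-relatedness matrix ``A^-1`` assembled by
  Henderson's recursive rules with inbreeding-corrected Mendelian-sampling
  variances.

Individuals with one unknown parent are treated as having a phantom founder
parent of the NATIVE group (q = 0, f = 0, unrelated to everyone); this keeps
the native group as the zero-mean base population.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = ""  # canonical encoding of a missing parent after parsing

IMMIGRANT = "IMMIGRANT"
NATIVE = "NATIVE"

_SEX_CODES = {
    "F": "F", "FEMALE": "F", "0": "F",
    "M": "M", "MALE": "M", "1": "M",
    "": "UNKNOWN", "U": "UNKNOWN", "UNKNOWN": "UNKNOWN", "NA": "UNKNOWN",
}
_TRUE_TOKENS = {"1", "TRUE", "T", "YES", "Y", "IMMIGRANT"}
_FALSE_TOKENS = {"0", "FALSE", "F", "NO", "N", "", "NA", "NATIVE"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, missing parents...)."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member; ``sire``/``dam`` are ids or ``UNKNOWN`` ("")."""

    id: str
    sire: str = UNKNOWN
    dam: str = UNKNOWN
    cohort: int | None = None
    sex: str = "UNKNOWN"
    immigrant_founder: bool = False


class Pedigree:
    """Topologically ordered pedigree (parents always precede offspring).

    Construction validates that every named parent exists, that the parent
    graph is acyclic, and that flagged immigrant founders have no parents.
    The stored order is a Kahn topological sort with ties broken by input
    order, so matrix indexing is reproducible for a given input file.
    """

    def __init__(self, individuals: Sequence[Individual]):
        self.individuals: list[Individual] = _toposort(list(individuals))
        self.index: dict[str, int] = {
            ind.id: k for k, ind in enumerate(self.individuals)
        }
        n = len(self.individuals)
        self.sire_idx = np.full(n, -1, dtype=np.int64)
        self.dam_idx = np.full(n, -1, dtype=np.int64)
        for k, ind in enumerate(self.individuals):
            if ind.sire != UNKNOWN:
                self.sire_idx[k] = self.index[ind.sire]
            if ind.dam != UNKNOWN:
                self.dam_idx[k] = self.index[ind.dam]
            if ind.immigrant_founder and (ind.sire != UNKNOWN or ind.dam != UNKNOWN):
                raise PedigreeError(
                    f"individual {ind.id!r} is flagged as an immigrant founder "
                    "but has a known parent"
                )
        self._f: np.ndarray | None = None

    # -- basic container protocol ------------------------------------------
    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    def __contains__(self, id: str) -> bool:
        return id in self.index

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    @property
    def cohorts(self) -> np.ndarray:
        return np.array(
            [np.nan if i.cohort is None else i.cohort for i in self.individuals]
        )

    def is_founder(self, k: int) -> bool:
        """True iff both parents are unknown."""
        return self.sire_idx[k] < 0 and self.dam_idx[k] < 0

    @property
    def founder_mask(self) -> np.ndarray:
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [i.sire for i in self.individuals],
                "dam": [i.dam for i in self.individuals],
                "cohort": [i.cohort for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "immigrant": [int(i.immigrant_founder) for i in self.individuals],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    # -- kinship / inbreeding ----------------------------------------------
    def inbreeding(self) -> np.ndarray:
        """Wright's f for every individual: kinship of its parents.

        Exact recursive kinship with memoisation; a missing parent is a
        phantom founder unrelated to everyone, so f = 0 whenever either
        parent is unknown.
        """
        if self._f is None:
            self._f = _inbreeding_vector(self.sire_idx, self.dam_idx)
        return self._f

    def kinship(self, a: str, b: str) -> float:
        """Exact pairwise kinship coefficient between two individuals."""
        memo: dict[tuple[int, int], float] = {}
        return _kinship(self.index[a], self.index[b],
                        self.sire_idx, self.dam_idx, memo)


def _toposort(individuals: list[Individual]) -> list[Individual]:
    ids = [ind.id for ind in individuals]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise PedigreeError(f"duplicate individual id {i!r}")
            seen.add(i)
    pos = {id: k for k, id in enumerate(ids)}
    for ind in individuals:
        for parent in (ind.sire, ind.dam):
            if parent != UNKNOWN and parent not in pos:
                raise PedigreeError(
                    f"individual {ind.id!r} references missing parent {parent!r}"
                )
    # Kahn's algorithm; ready set processed in input order for determinism.
    children: dict[int, list[int]] = {k: [] for k in range(len(individuals))}
    indeg = [0] * len(individuals)
    for k, ind in enumerate(individuals):
        for parent in (ind.sire, ind.dam):
            if parent != UNKNOWN:
                children[pos[parent]].append(k)
                indeg[k] += 1
    import heapq

    ready = [k for k in range(len(individuals)) if indeg[k] == 0]
    heapq.heapify(ready)
    out: list[Individual] = []
    while ready:
        k = heapq.heappop(ready)
        out.append(individuals[k])
        for c in children[k]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, c)
    if len(out) != len(individuals):
        remaining = {k for k in range(len(individuals)) if indeg[k] > 0}
        # walk parent links within the remaining set until we revisit a node:
        # that node provably lies on a cycle
        k = next(iter(remaining))
        seen: set[int] = set()
        while k not in seen:
            seen.add(k)
            ind = individuals[k]
            k = next(
                pos[p] for p in (ind.sire, ind.dam)
                if p != UNKNOWN and pos[p] in remaining
            )
        raise PedigreeError(
            f"pedigree contains a cycle through individual {individuals[k].id!r}"
        )
    return out


def _kinship(i: int, j: int, sire: np.ndarray, dam: np.ndarray,
             memo: dict[tuple[int, int], float]) -> float:
    """Recursive kinship phi(i, j); -1 denotes a phantom (unknown) parent."""
    if i < 0 or j < 0:
        return 0.0
    if i < j:
        i, j = j, i
    key = (i, j)
    val = memo.get(key)
    if val is not None:
        return val
    if i == j:
        val = 0.5 + 0.5 * _kinship(sire[i], dam[i], sire, dam, memo)
    else:
        # i is the later individual in topological order, so j is never a
        # descendant of i and we may recurse through i's parents
        val = 0.5 * (
            _kinship(sire[i], j, sire, dam, memo)
            + _kinship(dam[i], j, sire, dam, memo)
        )
    memo[key] = val
    return val


def _inbreeding_vector(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    n = len(sire)
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * n + 1000))
    try:
        memo: dict[tuple[int, int], float] = {}
        f = np.zeros(n)
        for k in range(n):
            if sire[k] >= 0 and dam[k] >= 0:
                f[k] = _kinship(sire[k], dam[k], sire, dam, memo)
    finally:
        sys.setrecursionlimit(old)
    return f


# ---------------------------------------------------------------------------
# reading / pruning / group assignment
# ---------------------------------------------------------------------------

def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV (columns id, sire, dam, cohort, sex, immigrant).

    Unknown parents are encoded by an empty field or "NA". The returned
    pedigree is topologically sorted regardless of row order in the file.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return pedigree_from_frame(df)


def pedigree_from_frame(df: pd.DataFrame) -> Pedigree:
    required = {"id", "sire", "dam", "cohort", "sex", "immigrant"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"pedigree table lacks columns: {sorted(missing)}")

    def _parent(tok) -> str:
        tok = "" if tok is None else str(tok).strip()
        return UNKNOWN if tok.upper() in ("", "NA", "NAN") else tok

    def _cohort(tok):
        tok = str(tok).strip()
        if tok.upper() in ("", "NA", "NAN"):
            return None
        return int(float(tok))

    def _flag(tok) -> bool:
        tok = str(tok).strip().upper()
        if tok in _TRUE_TOKENS:
            return True
        if tok in _FALSE_TOKENS:
            return False
        raise PedigreeError(f"unparseable immigrant flag {tok!r}")

    inds = []
    for row in df.itertuples(index=False):
        sex = _SEX_CODES.get(str(row.sex).strip().upper())
        if sex is None:
            raise PedigreeError(f"unparseable sex code {row.sex!r} for id {row.id!r}")
        inds.append(
            Individual(
                id=str(row.id).strip(),
                sire=_parent(row.sire),
                dam=_parent(row.dam),
                cohort=_cohort(row.cohort),
                sex=sex,
                immigrant_founder=_flag(row.immigrant),
            )
        )
    return Pedigree(inds)


def prune_to_phenotyped(ped: Pedigree, phenotyped_ids: Iterable[str]) -> Pedigree:
    """Restrict the pedigree to phenotyped individuals plus all their ancestors.

    This is the ancestor closure: everything that can contribute genes to a
    phenotyped individual is retained, nothing else.
    """
    wanted = list(dict.fromkeys(phenotyped_ids))
    if not wanted:
        raise PedigreeError("empty phenotyped set")
    unknown = [i for i in wanted if i not in ped.index]
    if unknown:
        raise PedigreeError(f"phenotyped ids not in pedigree: {unknown[:5]}")
    keep: set[int] = set()
    stack = [ped.index[i] for i in wanted]
    while stack:
        k = stack.pop()
        if k in keep:
            continue
        keep.add(k)
        for p in (ped.sire_idx[k], ped.dam_idx[k]):
            if p >= 0:
                stack.append(p)
    return Pedigree([ped.individuals[k] for k in sorted(keep)])


def assign_groups(ped: Pedigree) -> dict[str, str]:
    """Assign every founder (both parents unknown) to IMMIGRANT or NATIVE.

    Founders flagged as immigrants form the immigrant group; all other
    parentless individuals are natives. On a pruned pedigree, retention
    already implies each founder contributed descendants to the phenotyped
    set, so no explicit contribution test is needed.
    """
    out: dict[str, str] = {}
    for k, ind in enumerate(ped.individuals):
        if ped.is_founder(k):
            out[ind.id] = IMMIGRANT if ind.immigrant_founder else NATIVE
    return out


@dataclass
class GroupCoefficients:
    """Per-individual immigrant-group fraction q and inbreeding f."""

    ids: list[str]
    q: np.ndarray
    f: np.ndarray
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {i: k for k, i in enumerate(self.ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "q": self.q, "f": self.f})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def group_coefficients(ped: Pedigree, ga: Mapping[str, str]) -> GroupCoefficients:
    """Compute q by the parental-averaging recursion and f by exact kinship.

    q of a founder is 1 (IMMIGRANT) or 0 (NATIVE); for non-founders
    q_i = (q_sire + q_dam) / 2, with an unknown parent contributing the
    phantom-native value 0. f_i is the kinship of i's parents (0 for
    founders and for individuals with an unknown parent).
    """
    n = len(ped)
    q = np.zeros(n)
    for k, ind in enumerate(ped.individuals):
        if ped.is_founder(k):
            grp = ga.get(ind.id)
            if grp is None:
                raise PedigreeError(f"founder {ind.id!r} missing a group assignment")
            q[k] = 1.0 if grp == IMMIGRANT else 0.0
        else:
            qs = q[ped.sire_idx[k]] if ped.sire_idx[k] >= 0 else 0.0
            qd = q[ped.dam_idx[k]] if ped.dam_idx[k] >= 0 else 0.0
            q[k] = 0.5 * (qs + qd)
    return GroupCoefficients(ids=ped.ids, q=q, f=ped.inbreeding().copy())


# ---------------------------------------------------------------------------
# inverse additive-relatedness matrix
# ---------------------------------------------------------------------------

@dataclass
class RelatednessStructure:
    """Sparse A^-1 with the Mendelian-sampling variance diagonal used to build it."""

    ids: list[str]
    a_inv: sparse.csr_matrix
    d: np.ndarray  # Mendelian-sampling variance per individual

    def write(self, matrix_path, index_path) -> None:
        coo = self.a_inv.tocoo()
        pd.DataFrame({"i": coo.row, "j": coo.col, "value": coo.data}).to_csv(
            matrix_path, index=False
        )
        pd.DataFrame({"index": range(len(self.ids)), "id": self.ids}).to_csv(
            index_path, index=False
        )


def mendelian_variances(ped: Pedigree, f: np.ndarray | None = None) -> np.ndarray:
    """Mendelian-sampling variance d_i (as a fraction of V_A).

    Both parents known: 0.5 - 0.25 (f_sire + f_dam); one known parent:
    0.75 - 0.25 f_known (the phantom parent is a non-inbred founder);
    founders: 1.
    """
    if f is None:
        f = ped.inbreeding()
    n = len(ped)
    d = np.ones(n)
    s, m = ped.sire_idx, ped.dam_idx
    both = (s >= 0) & (m >= 0)
    d[both] = 0.5 - 0.25 * (f[s[both]] + f[m[both]])
    one_s = (s >= 0) & (m < 0)
    d[one_s] = 0.75 - 0.25 * f[s[one_s]]
    one_m = (s < 0) & (m >= 0)
    d[one_m] = 0.75 - 0.25 * f[m[one_m]]
    return d


def a_inverse(ped: Pedigree, gc: GroupCoefficients | None = None) -> RelatednessStructure:
    """Assemble sparse A^-1 by Henderson's rules, inbreeding-corrected."""
    f = gc.f if gc is not None else ped.inbreeding()
    d = mendelian_variances(ped, f)
    n = len(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for k in range(n):
        b = 1.0 / d[k]
        parents = [p for p in (ped.sire_idx[k], ped.dam_idx[k]) if p >= 0]
        rows.append(k); cols.append(k); vals.append(b)
        for p in parents:
            rows += [k, p]; cols += [p, k]; vals += [-b / 2, -b / 2]
        for p1 in parents:
            for p2 in parents:
                rows.append(p1); cols.append(p2); vals.append(b / 4)
    a_inv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelatednessStructure(ids=ped.ids, a_inv=a_inv, d=d)
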
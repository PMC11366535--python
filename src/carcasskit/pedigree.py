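"""Pedigree handling for the animal model.

Reads 3-column pedigree files, restricts them to phenotyped animals plus a
fixed number of ancestral generations, orders animals parents-first, computes
inbreeding coefficients (Meuwissen & Luo recursion) and builds the numerator
relationship matrix A (tabular method, dense — used as an oracle) and its
sparse inverse (Henderson's rules with inbreeding).
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Pedigree",
    "PedigreeError",
    "read_pedigree_file",
    "read_and_trace",
    "a_matrix_tabular",
    "a_inverse",
]

_UNKNOWN_TOKENS = {"0", "", ".", "na", "nan", "none", "unknown"}


class PedigreeError(ValueError):
    """Invalid pedigree structure (cycles, conflicting duplicates, ...)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree with inbreeding coefficients.

    ``sire``/``dam`` hold positions into the ordered animal list, ``-1`` for
    an unknown parent.  Parents always precede their offspring.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    inbreeding: np.ndarray
    index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {a: i for i, a in enumerate(self.ids)}
        for i in range(self.n_animals):
            for p in (self.sire[i], self.dam[i]):
                if p >= i:
                    raise PedigreeError(
                        f"pedigree not ordered parents-first at position {i}"
                    )

    @property
    def n_animals(self) -> int:
        return len(self.ids)

    def positions_of(self, animal_ids) -> np.ndarray:
        """Map external animal identifiers to pedigree positions.

        Falls back to string comparison so numeric ids match pedigrees read
        from text files.
        """
        out = np.empty(len(animal_ids), dtype=np.int64)
        for k, a in enumerate(animal_ids):
            if a in self.index:
                out[k] = self.index[a]
            elif str(a) in self.index:
                out[k] = self.index[str(a)]
            else:
                raise KeyError(f"animal {a!r} not in pedigree")
        return out

    @property
    def mendelian_variance_factor(self) -> np.ndarray:
        """Per-animal Mendelian sampling variance as a fraction of sigma2_a.

        1 for both parents unknown, 0.75 - F_p/4 for one known parent,
        0.5 - (F_s + F_d)/4 for both known.  These are the diagonal elements
        of the D matrix in the A = T D T' decomposition.
        """
        return _d_values(self.sire, self.dam, self.inbreeding)

    @classmethod
    def from_parent_map(cls, records: dict) -> "Pedigree":
        """Build from ``{animal: (sire_or_None, dam_or_None), ...}``."""
        order = _topological_order(records)
        pos = {a: i for i, a in enumerate(order)}
        n = len(order)
        sire = np.full(n, -1, dtype=np.int64)
        dam = np.full(n, -1, dtype=np.int64)
        for a, (s, d) in records.items():
            i = pos[a]
            if s is not None:
                sire[i] = pos[s]
            if d is not None:
                dam[i] = pos[d]
        inb = inbreeding_coefficients(sire, dam)
        return cls(np.asarray(order, dtype=object), sire, dam, inb, pos)


def _topological_order(records: dict) -> list:
    """Parents-first ordering via Kahn's algorithm; names a cycle on failure."""
    known = set(records)
    n_parents = {a: 0 for a in records}
    children = {a: [] for a in records}
    for a, (s, d) in records.items():
        for p in (s, d):
            if p is not None and p in known:
                n_parents[a] += 1
                children[p].append(a)
    ready = deque(sorted((a for a, k in n_parents.items() if k == 0), key=str))
    order = []
    while ready:
        a = ready.popleft()
        order.append(a)
        for c in children[a]:
            n_parents[c] -= 1
            if n_parents[c] == 0:
                ready.append(c)
    if len(order) < len(records):
        g = nx.DiGraph()
        for a, (s, d) in records.items():
            for p in (s, d):
                if p is not None and p in known:
                    g.add_edge(p, a)
        cycle = [e[0] for e in nx.find_cycle(g)]
        raise PedigreeError(f"pedigree contains a cycle: {' -> '.join(map(str, cycle))}")
    return order


def read_pedigree_file(path) -> pd.DataFrame:
    """Read a 3-column (animal, sire, dam) delimited text file.

    A header row is accepted if the first field is non-numeric and matches a
    common column name; unknown parents are coded 0, blank or NA.
    """
    path = Path(path)
    first = path.read_text().lstrip().splitlines()[0]
    tokens = [t.strip().lower() for t in first.replace(",", " ").split()]
    header = 0 if tokens and tokens[0] in {"animal", "id", "calf", "individual"} else None
    df = pd.read_csv(path, header=header, sep=None, engine="python", dtype=str)
    if df.shape[1] < 3:
        raise PedigreeError(f"{path}: expected 3 columns (animal, sire, dam)")
    df = df.iloc[:, :3]
    df.columns = ["animal", "sire", "dam"]
    return df


def _clean_parent(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    if text.lower() in _UNKNOWN_TOKENS:
        return None
    return text


def read_and_trace(pedigree, phenotyped_ids, max_generations: int = 5) -> Pedigree:
    """Restrict a pedigree to phenotyped animals plus ``max_generations`` of ancestors.

    ``pedigree`` is a file path or a DataFrame with columns (animal, sire,
    dam).  An animal's generation is its shortest parent-path distance to a
    phenotyped descendant (phenotyped animals are generation 0, their parents
    generation 1).  Parents of animals at the cutoff become unknown.
    Phenotyped animals absent from the file are kept as founders.
    """
    if not isinstance(pedigree, pd.DataFrame):
        pedigree = read_pedigree_file(pedigree)
    parent_of: dict = {}
    for row in pedigree.itertuples(index=False):
        a = str(row.animal).strip()
        s, d = _clean_parent(row.sire), _clean_parent(row.dam)
        if a in parent_of and parent_of[a] != (s, d):
            raise PedigreeError(f"animal {a!r} listed twice with conflicting parents")
        parent_of[a] = (s, d)

    phenotyped = [str(a).strip() for a in phenotyped_ids]
    generation = {a: 0 for a in phenotyped}
    frontier = deque(phenotyped)
    while frontier:
        a = frontier.popleft()
        g = generation[a]
        if g >= max_generations:
            continue
        for p in parent_of.get(a, (None, None)):
            if p is not None and generation.get(p, np.inf) > g + 1:
                generation[p] = g + 1
                frontier.append(p)

    kept: dict = {}
    for a, g in generation.items():
        s, d = parent_of.get(a, (None, None))
        if g >= max_generations:  # parents beyond the cutoff become unknown
            s = d = None
        else:
            s = s if (s in generation) else None
            d = d if (d in generation) else None
        kept[a] = (s, d)
    return Pedigree.from_parent_map(kept)


def _d_values(sire: np.ndarray, dam: np.ndarray, inb: np.ndarray) -> np.ndarray:
    n = len(sire)
    d = np.empty(n)
    for i in range(n):
        s, t = sire[i], dam[i]
        if s < 0 and t < 0:
            d[i] = 1.0
        elif s < 0:
            d[i] = 0.75 - 0.25 * inb[t]
        elif t < 0:
            d[i] = 0.75 - 0.25 * inb[s]
        else:
            d[i] = 0.5 - 0.25 * (inb[s] + inb[t])
    return d


def inbreeding_coefficients(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Meuwissen & Luo recursion on an ordered pedigree.

    For each animal the diagonal A_ii = sum_j L_ij^2 D_j is accumulated by
    walking its ancestor set once, highest index first; F_i = A_ii - 1.
    """
    n = len(sire)
    inb = np.zeros(n)
    dvals = np.empty(n)
    for i in range(n):
        s, t = sire[i], dam[i]
        fs = inb[s] if s >= 0 else 0.0
        ft = inb[t] if t >= 0 else 0.0
        if s < 0 and t < 0:
            dvals[i] = 1.0
        elif s < 0 or t < 0:
            dvals[i] = 0.75 - 0.25 * (fs + ft)
        else:
            dvals[i] = 0.5 - 0.25 * (fs + ft)
        if s < 0 or t < 0:
            inb[i] = 0.0
            continue
        coeff = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            l = coeff.pop(j, 0.0)
            if l == 0.0:
                continue
            aii += l * l * dvals[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    if p not in coeff:
                        coeff[p] = 0.0
                        heapq.heappush(heap, -p)
                    coeff[p] += 0.5 * l
        inb[i] = aii - 1.0
    return inb


def a_matrix_tabular(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular recursion.

    O(n^2) memory — intended as the oracle for :func:`a_inverse` on small
    pedigrees, not for production-size ones.
    """
    n = ped.n_animals
    a = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        asd = a[s, d] if (s >= 0 and d >= 0) else 0.0
        a[i, i] = 1.0 + 0.5 * asd
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * a[j, s]
            if d >= 0:
                val += 0.5 * a[j, d]
            a[i, j] = a[j, i] = val
    return a


def a_inverse(ped: Pedigree) -> sp.csr_matrix:
    """Sparse inverse of A by Henderson's rules, with inbreeding.

    Each animal contributes alpha_i = 1/D_i to its own diagonal, -alpha_i/2
    to animal-parent cells and alpha_i/4 to parent-parent cells, where D_i is
    the Mendelian sampling variance fraction from the inbreeding recursion.
    """
    n = ped.n_animals
    alpha = 1.0 / _d_values(ped.sire, ped.dam, ped.inbreeding)
    rows, cols, vals = [], [], []
    for i in range(n):
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        rows.append(i)
        cols.append(i)
        vals.append(alpha[i])
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * alpha[i], -0.5 * alpha[i]]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(0.25 * alpha[i])
    out = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    out.sum_duplicates()
    return out
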
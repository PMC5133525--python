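"""Pedigree parsing and pedigree-based relatedness matrices.

The additive kinship matrix Phi and the dominance matrix Delta are the two
structured components of the polygenic covariance

    Omega = 2 * Phi * sigma2_a + Delta * sigma2_d,

valid when inbreeding is minimal or absent.  phi_ij is the probability that a
random allele drawn from individual i and one drawn from j are identical by
descent (IBD); Delta_ij is the probability that i and j share both alleles
IBD.  Both are functions of the condensed (Jacquard) identity coefficients;
under no inbreeding they reduce to the closed forms computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Internal individual key: (family id, individual id).
Key = tuple[str, str]

MISSING_PARENT = {"0", "", "."}


class PedigreeError(ValueError):
    """Structural or validation problem in a pedigree."""


class CycleError(PedigreeError):
    """An individual is its own ancestor."""


@dataclass
class Pedigree:
    """A directed acyclic family structure.

    Attributes
    ----------
    members : list of (family, individual) keys, in file/topological order.
    parents : key -> (father key or None, mother key or None).  An individual
        has either zero recorded parents (a founder) or two.
    sex : key -> sex code (1 male, 2 female, 0 unknown), informational only.
    """

    members: list[Key]
    parents: dict[Key, tuple[Key | None, Key | None]]
    sex: dict[Key, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {k: i for i, k in enumerate(self.members)}
        if len(self._index) != len(self.members):
            dupes = pd.Series(self.members).duplicated()
            raise PedigreeError(
                f"duplicate individual id(s): {pd.Series(self.members)[dupes].tolist()}"
            )
        for k, (f, m) in self.parents.items():
            if (f is None) != (m is None):
                raise PedigreeError(
                    f"individual {k} has exactly one recorded parent; "
                    "records must name zero or two parents"
                )
        self._topo = self._topological_order()
        self._rank = {k: i for i, k in enumerate(self._topo)}

    # -- structure ---------------------------------------------------------

    def _topological_order(self) -> list[Key]:
        """Founders-first order; raises CycleError on ancestral cycles."""
        indeg = {k: 0 for k in self.members}
        children: dict[Key, list[Key]] = {k: [] for k in self.members}
        for k, (f, m) in self.parents.items():
            for p in (f, m):
                if p is not None:
                    indeg[k] += 1
                    children[p].append(k)
        queue = [k for k in self.members if indeg[k] == 0]
        order: list[Key] = []
        while queue:
            k = queue.pop()
            order.append(k)
            for c in children[k]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(self.members):
            stuck = next(k for k in self.members if indeg[k] > 0)
            raise CycleError(f"pedigree cycle detected involving individual {stuck}")
        return order

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, ind) -> bool:
        try:
            self.resolve(ind)
        except KeyError:
            return False
        return True

    def resolve(self, ind) -> Key:
        """Map a bare individual id or a (family, id) pair to the internal key.

        Bare ids are accepted only when unambiguous across families.
        """
        if isinstance(ind, tuple):
            key = (str(ind[0]), str(ind[1]))
            if key not in self._index:
                raise KeyError(f"unknown individual {key}")
            return key
        matches = [k for k in self.members if k[1] == str(ind)]
        if not matches:
            raise KeyError(f"unknown individual {ind!r}")
        if len(matches) > 1:
            raise KeyError(f"individual id {ind!r} is ambiguous across families; pass (family, id)")
        return matches[0]

    def is_founder(self, ind) -> bool:
        return self.parents[self.resolve(ind)][0] is None

    @property
    def founders(self) -> list[Key]:
        return [k for k in self.members if self.parents[k][0] is None]

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for fam, _ in self.members:
            seen.setdefault(fam)
        return list(seen)

    def topological_order(self) -> list[Key]:
        return list(self._topo)

    # -- kinship recursion -------------------------------------------------

    def kinship(self, i, j) -> float:
        """Kinship coefficient phi_ij by the standard recursion.

        phi_ii = (1 + phi_fm)/2 with f, m the parents of i (0.5 for a
        founder); for i != j, recursing on the individual that appears later
        in a topological order guarantees we never recurse on an ancestor:
        phi_ij = (phi_fj + phi_mj)/2, founders pairwise unrelated.
        """
        ki, kj = self.resolve(i), self.resolve(j)
        memo: dict[tuple[Key, Key], float] = getattr(self, "_kin_memo", None) or {}
        self._kin_memo = memo
        return self._phi(ki, kj, memo)

    def _phi(self, a: Key, b: Key, memo) -> float:
        if self._rank[a] < self._rank[b]:
            a, b = b, a  # a is the later (non-ancestor of b) individual
        cached = memo.get((a, b))
        if cached is not None:
            return cached
        fa, ma = self.parents[a]
        if a == b:
            val = 0.5 if fa is None else 0.5 * (1.0 + self._phi(fa, ma, memo))
        elif fa is None:
            val = 0.0  # a is a founder and not an ancestor of b
        else:
            val = 0.5 * (self._phi(fa, b, memo) + self._phi(ma, b, memo))
        memo[(a, b)] = val
        return val

    def dominance(self, i, j) -> float:
        """Both-alleles-IBD probability Delta_ij under no inbreeding.

        Delta_ij = phi(f_i,f_j)*phi(m_i,m_j) + phi(f_i,m_j)*phi(m_i,f_j);
        Delta_ii = 1.  Founders (no recorded parents) paired with anyone else
        yield 0.  If either individual is detectably inbred (its parents have
        positive kinship) a warning is logged and the no-inbreeding
        approximation is still applied.
        """
        ki, kj = self.resolve(i), self.resolve(j)
        if ki == kj:
            return 1.0
        fi, mi = self.parents[ki]
        fj, mj = self.parents[kj]
        if fi is None or fj is None:
            return 0.0
        for ind, (f, m) in ((ki, (fi, mi)), (kj, (fj, mj))):
            if self.kinship(f, m) > 0:
                logger.warning(
                    "individual %s is inbred (parental kinship %.4g); "
                    "dominance coefficient uses the no-inbreeding approximation",
                    ind, self.kinship(f, m),
                )
        return (
            self.kinship(fi, fj) * self.kinship(mi, mj)
            + self.kinship(fi, mj) * self.kinship(mi, fj)
        )

    def inbreeding_audit(self) -> float:
        """Maximum parental kinship over all non-founders.

        A positive value means some individuals are inbred and the
        no-inbreeding closed forms for Delta (and phi_ii = 0.5) are
        approximations; users can judge the severity from the magnitude.
        """
        worst = 0.0
        for k in self.members:
            f, m = self.parents[k]
            if f is not None:
                worst = max(worst, self.kinship(f, m))
        return worst


@dataclass
class RelatednessMatrices:
    """Kinship (phi) and dominance (delta) matrices over a fixed sample order."""

    phi: np.ndarray
    delta: np.ndarray
    sample_order: list[Key]

    def __post_init__(self) -> None:
        n = len(self.sample_order)
        if self.phi.shape != (n, n) or self.delta.shape != (n, n):
            raise ValueError("matrix dimensions do not match sample_order")

    @property
    def n(self) -> int:
        return len(self.sample_order)

    def subset(self, sample: Sequence[Key]) -> "RelatednessMatrices":
        pos = {k: i for i, k in enumerate(self.sample_order)}
        idx = np.array([pos[k] for k in sample])
        return RelatednessMatrices(
            self.phi[np.ix_(idx, idx)], self.delta[np.ix_(idx, idx)], list(sample)
        )

    def write_tsv(self, phi_path, delta_path) -> None:
        """Square TSV with an id header row and id index column."""
        ids = [f"{f}:{i}" for f, i in self.sample_order]
        pd.DataFrame(self.phi, index=ids, columns=ids).to_csv(phi_path, sep="\t")
        pd.DataFrame(self.delta, index=ids, columns=ids).to_csv(delta_path, sep="\t")

    def write_gcta(self, path) -> None:
        """Lower-triangle text: row index, col index (1-based), n, value of 2*phi."""
        with open(path, "w") as fh:
            n = self.n
            for i in range(n):
                for j in range(i + 1):
                    fh.write(f"{i + 1}\t{j + 1}\t{n}\t{2 * self.phi[i, j]:.10g}\n")


def parse_pedigree(path, dialect: str = "ped") -> Pedigree:
    """Read a PLINK-dialect PED/FAM pedigree file.

    Whitespace-delimited columns FID IID PAT MAT [SEX [PHENO ...]]; '0' (or
    blank/'.') marks an unknown parent.  Parents referenced but not listed as
    rows are auto-created as founders with a logged warning.  Trailing
    genotype columns of a full PED file are ignored.
    """
    if dialect not in ("ped", "fam"):
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 4:
                raise PedigreeError(f"{path}:{lineno}: expected at least 4 columns")
            fid, iid, pat, mat = parts[:4]
            sex = int(parts[4]) if len(parts) > 4 and parts[4].isdigit() else 0
            rows.append((fid, iid, pat, mat, sex))
    members: list[Key] = []
    parents: dict[Key, tuple[Key | None, Key | None]] = {}
    sexes: dict[Key, int] = {}
    seen: set[Key] = set()
    for fid, iid, pat, mat, sex in rows:
        key = (fid, iid)
        if key in seen:
            raise PedigreeError(f"duplicate individual id {key}")
        seen.add(key)
    for fid, iid, pat, mat, sex in rows:
        key = (fid, iid)
        f = None if pat in MISSING_PARENT else (fid, pat)
        m = None if mat in MISSING_PARENT else (fid, mat)
        if (f is None) != (m is None):
            raise PedigreeError(
                f"individual {key} has one known and one unknown parent"
            )
        for p, code in ((f, 1), (m, 2)):
            if p is not None and p not in seen:
                logger.warning(
                    "parent %s referenced but not listed; created as founder", p
                )
                seen.add(p)
                members.append(p)
                parents[p] = (None, None)
                sexes[p] = code
        members.append(key)
        parents[key] = (f, m)
        sexes[key] = sex
    return Pedigree(members=members, parents=parents, sex=sexes)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write a PLINK FAM file (FID IID PAT MAT SEX PHENO) with PHENO = -9."""
    with open(path, "w") as fh:
        for k in ped.members:
            f, m = ped.parents[k]
            fh.write(
                "\t".join(
                    [k[0], k[1], f[1] if f else "0", m[1] if m else "0",
                     str(ped.sex.get(k, 0)), "-9"]
                )
                + "\n"
            )


def kinship_coefficient(ped: Pedigree, i, j) -> float:
    """Kinship coefficient phi_ij; see :meth:`Pedigree.kinship`."""
    return ped.kinship(i, j)


def dominance_coefficient(ped: Pedigree, i, j) -> float:
    """Both-alleles-IBD probability Delta_ij; see :meth:`Pedigree.dominance`."""
    return ped.dominance(i, j)


def build_matrices(ped: Pedigree, sample: Iterable | None = None) -> RelatednessMatrices:
    """Compute Phi and Delta over `sample` (default: every pedigree member).

    Uses the tabular form of the kinship recursion over a topological order,
    vectorised row by row, then the no-inbreeding closed form for Delta via
    parent-index lookups into Phi.  Equivalent to the pairwise recursion but
    O(n^2) with numpy row operations.
    """
    if sample is None:
        keys = list(ped.members)
    else:
        keys = [ped.resolve(s) for s in sample]
    if not keys:
        raise PedigreeError("empty sample")

    topo = ped.topological_order()
    idx = {k: i for i, k in enumerate(topo)}
    n_all = len(topo)
    fa = np.full(n_all, -1, dtype=np.int64)
    mo = np.full(n_all, -1, dtype=np.int64)
    for k in topo:
        f, m = ped.parents[k]
        if f is not None:
            fa[idx[k]] = idx[f]
            mo[idx[k]] = idx[m]

    phi = np.zeros((n_all, n_all))
    for i in range(n_all):
        if fa[i] < 0:
            phi[i, i] = 0.5
        else:
            phi[i, :i] = 0.5 * (phi[fa[i], :i] + phi[mo[i], :i])
            phi[:i, i] = phi[i, :i]
            phi[i, i] = 0.5 * (1.0 + phi[fa[i], mo[i]])

    nonf = fa >= 0
    delta = np.zeros((n_all, n_all))
    if nonf.any():
        F, M = fa[nonf], mo[nonf]
        delta[np.ix_(nonf, nonf)] = (
            phi[np.ix_(F, F)] * phi[np.ix_(M, M)]
            + phi[np.ix_(F, M)] * phi[np.ix_(M, F)]
        )
    np.fill_diagonal(delta, 1.0)

    rows = np.array([idx[k] for k in keys])
    return RelatednessMatrices(
        phi=phi[np.ix_(rows, rows)], delta=delta[np.ix_(rows, rows)], sample_order=keys
    )
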
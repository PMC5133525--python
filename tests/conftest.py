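"""Shared fixtures: hand-built pedigrees, simulated studies, and an
independent Monte-Carlo gene-dropping oracle for IBD probabilities."""

from __future__ import annotations

import numpy as np
import pytest

from pedlasso import SimulationConfig, simulate_study
from pedlasso.pedigree import Pedigree


def make_pedigree(rows):
    """Build a Pedigree from (iid, father, mother) rows in one family 'T'."""
    members, parents, sex = [], {}, {}
    for iid, f, m in rows:
        key = ("T", iid)
        members.append(key)
        parents[key] = (("T", f), ("T", m)) if f else (None, None)
        sex[key] = 0
    return Pedigree(members=members, parents=parents, sex=sex)


@pytest.fixture
def trio():
    return make_pedigree([("F", None, None), ("M", None, None), ("C", "F", "M")])


@pytest.fixture
def nuclear():
    return make_pedigree(
        [("F", None, None), ("M", None, None), ("C1", "F", "M"), ("C2", "F", "M")]
    )


@pytest.fixture
def three_gen():
    """Three generations: grandparents, two married sibs, three grandchildren.

    C1a/C1b are full sibs; C2 is their first cousin (phi = 1/16).
    """
    return make_pedigree(
        [
            ("GF", None, None), ("GM", None, None),
            ("P1", "GF", "GM"), ("P2", "GF", "GM"),
            ("S1", None, None), ("S2", None, None),
            ("C1a", "P1", "S1"), ("C1b", "P1", "S1"),
            ("C2", "P2", "S2"),
        ]
    )


@pytest.fixture
def double_cousins():
    """D1 and D2 are double first cousins: phi = 1/8, Delta = 1/16."""
    return make_pedigree(
        [
            ("A1", None, None), ("A2", None, None),
            ("B1", None, None), ("B2", None, None),
            ("a1", "A1", "A2"), ("a2", "A1", "A2"),
            ("b1", "B1", "B2"), ("b2", "B1", "B2"),
            ("D1", "a1", "b1"), ("D2", "a2", "b2"),
        ]
    )


def mc_ibd(ped: Pedigree, n_loci: int, seed: int):
    """Monte-Carlo gene-dropping estimates of phi and Delta with standard errors.

    Founders carry uniquely labelled alleles; each non-founder inherits one
    uniformly chosen allele per parent, independently at each of `n_loci`
    simulated loci.  Returns (phi_hat, delta_hat, phi_se, delta_se) as dense
    arrays over ped.members order.  Deliberately independent of the package's
    recursion: the only shared input is the pedigree structure.
    """
    rng = np.random.default_rng(seed)
    topo = ped.topological_order()
    idx = {k: i for i, k in enumerate(topo)}
    n = len(topo)
    loci = np.arange(n_loci)
    alleles = np.zeros((n, 2, n_loci), dtype=np.int32)
    for k in topo:
        i = idx[k]
        f, m = ped.parents[k]
        if f is None:
            alleles[i, 0] = 2 * i
            alleles[i, 1] = 2 * i + 1
        else:
            alleles[i, 0] = alleles[idx[f], rng.integers(0, 2, n_loci), loci]
            alleles[i, 1] = alleles[idx[m], rng.integers(0, 2, n_loci), loci]

    order = [idx[k] for k in ped.members]
    m_ = len(order)
    phi = np.zeros((m_, m_))
    phi_se = np.zeros((m_, m_))
    delta = np.zeros((m_, m_))
    delta_se = np.zeros((m_, m_))
    for a in range(m_):
        ia = order[a]
        for b in range(a, m_):
            ib = order[b]
            if a == b:
                per_locus = 0.5 * (1.0 + (alleles[ia, 0] == alleles[ia, 1]))
                dl = np.ones(n_loci)
            else:
                eq = [
                    alleles[ia, x] == alleles[ib, y] for x in (0, 1) for y in (0, 1)
                ]
                # sum as integers: several of the four comparisons can hold at once
                per_locus = 0.25 * np.sum([e.astype(np.int8) for e in eq], axis=0)
                dl = ((eq[0] & eq[3]) | (eq[1] & eq[2])).astype(float)
            phi[a, b] = phi[b, a] = per_locus.mean()
            phi_se[a, b] = phi_se[b, a] = per_locus.std(ddof=1) / np.sqrt(n_loci)
            delta[a, b] = delta[b, a] = dl.mean()
            delta_se[a, b] = delta_se[b, a] = dl.std(ddof=1) / np.sqrt(n_loci)
    return phi, delta, phi_se, delta_se


@pytest.fixture(scope="session")
def small_study():
    """12 families of 22 (n = 264), strong-ish polygenic signal, no QTLs."""
    cfg = SimulationConfig(
        seed=31, n_families=12, sibship_sizes=(4, 3), n_snps=120, n_qtls=0,
        sigma2_a=4.0, sigma2_e=4.0,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def qtl_study():
    """10 families (n = 440) with two strong QTLs among 80 markers."""
    cfg = SimulationConfig(
        seed=3, n_families=10, n_snps=80, n_qtls=2, qtl_effect_sizes=2.0,
    )
    return simulate_study(cfg)
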
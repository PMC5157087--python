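"""Genome-wide gene-family (protein domain) expansion screen.

Counts, per species, the number of distinct proteins carrying each domain (a
domain occurring several times in one protein counts once).  Each domain is
then tested in the focal species against a background defined as the average
of the other species' counts, with a two-sided Fisher's exact test on the
2x2 table

    [[c_f, T_f - c_f], [round(mean c_o), round(mean T_o) - round(mean c_o)]]

where T is the species' total count of domain-bearing-protein incidences and
rounding is half-up.  P values are Benjamini-Hochberg adjusted; a domain is
called expanded when q < alpha (strict) and the focal count strictly exceeds
every other species' count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DomainAnnotation",
    "DomainCountMatrix",
    "ExpansionResult",
    "count_domains",
    "fisher_domain_test",
    "bh_adjust",
    "call_expansions",
    "run_expansion_screen",
]


@dataclass(frozen=True)
class DomainAnnotation:
    species: str
    protein_id: str
    domain_id: str


@dataclass(frozen=True)
class DomainCountMatrix:
    """Species x domain counts of distinct domain-bearing proteins."""

    species: tuple[str, ...]
    domains: tuple[str, ...]
    counts: np.ndarray  # shape (n_species, n_domains)
    focal: str

    def __post_init__(self) -> None:
        if self.focal not in self.species:
            raise ValueError(f"focal species {self.focal!r} not in matrix")
        if self.counts.shape != (len(self.species), len(self.domains)):
            raise ValueError("counts shape does not match labels")

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def focal_index(self) -> int:
        return self.species.index(self.focal)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.species),
                            columns=list(self.domains))


@dataclass(frozen=True)
class ExpansionResult:
    domain_id: str
    focal_count: int
    background_mean: float
    p: float
    q: float
    expanded: bool


def count_domains(annotations: list[DomainAnnotation], focal: str,
                  species: list[str] | None = None,
                  domains: list[str] | None = None) -> DomainCountMatrix:
    """Build the count matrix; each (species, protein, domain) counts once."""
    uniq = {(a.species, a.protein_id, a.domain_id) for a in annotations}
    sp = sorted({s for s, _, _ in uniq} | {focal} | set(species or []))
    dom = sorted({d for _, _, d in uniq} | set(domains or []))
    sidx = {s: i for i, s in enumerate(sp)}
    didx = {d: i for i, d in enumerate(dom)}
    counts = np.zeros((len(sp), len(dom)), dtype=int)
    for s, _p, d in uniq:
        counts[sidx[s], didx[d]] += 1
    return DomainCountMatrix(tuple(sp), tuple(dom), counts, focal)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def fisher_domain_test(m: DomainCountMatrix, domain: str) -> float:
    """Two-sided Fisher exact p for one domain vs the averaged background."""
    j = m.domains.index(domain)
    f = m.focal_index
    others = [i for i in range(len(m.species)) if i != f]
    if len(others) == 0:
        raise ValueError("need at least 2 species")
    c_f = int(m.counts[f, j])
    t_f = int(m.totals[f])
    c_o = _round_half_up(float(m.counts[others, j].mean()))
    t_o = _round_half_up(float(m.totals[others].mean()))
    if t_f == 0 or t_o == 0:
        warnings.warn("zero species total; Fisher test undefined, p set to 1")
        return 1.0
    table = [[c_f, t_f - c_f], [c_o, t_o - c_o]]
    return float(fisher_exact(table, alternative="two-sided")[1])


def bh_adjust(pvec) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(pvec, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def call_expansions(m: DomainCountMatrix, qvec=None, pvec=None,
                    alpha: float = 0.05) -> list[ExpansionResult]:
    """Per-domain expansion calls: q < alpha and strictly largest focal count."""
    if pvec is None:
        pvec = [fisher_domain_test(m, d) for d in m.domains]
    pvec = np.asarray(pvec, dtype=float)
    if qvec is None:
        qvec = bh_adjust(pvec)
    qvec = np.asarray(qvec, dtype=float)
    f = m.focal_index
    others = [i for i in range(len(m.species)) if i != f]
    out = []
    for j, d in enumerate(m.domains):
        c_f = int(m.counts[f, j])
        other_counts = m.counts[others, j]
        expanded = bool(qvec[j] < alpha
                        and (other_counts < c_f).all())
        out.append(ExpansionResult(d, c_f, float(other_counts.mean()),
                                   float(pvec[j]), float(qvec[j]), expanded))
    return out


def run_expansion_screen(m: DomainCountMatrix,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Count -> Fisher -> BH -> call, as a tidy per-domain table."""
    results = call_expansions(m, alpha=alpha)
    return pd.DataFrame([{
        "domain": r.domain_id,
        "focal_count": r.focal_count,
        "background_mean": r.background_mean,
        "p": r.p,
        "q": r.q,
        "expanded": r.expanded,
    } for r in results])
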
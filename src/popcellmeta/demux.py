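"""Pooled-library design validation and genotype-free identity assignment.

Libraries pool nuclei from three donors. Because the pooling design
guarantees that no *pair* of donors shares more than one library, the set of
libraries a donor appears in (its fingerprint) is unique, and anonymous
per-library genotype clusters can be assigned to donors without reference
genotypes: clusters are linked across libraries by variant-allele-fraction
concordance, linked components are matched to donors by fingerprint.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .datatypes import GenotypeSignature, PoolPlan

MIN_CONCORDANCE = 0.9
MIN_SHARED_SNPS = 100


@dataclass
class DesignReport:
    valid: bool
    violations: list[tuple[str, str]] = field(default_factory=list)


def validate_design(plan: PoolPlan) -> DesignReport:
    """Check that no unordered donor pair co-occurs in more than one library."""
    seen: dict[tuple[str, str], int] = {}
    for lib, samples in plan.members.items():
        donors = sorted({d for d, _ in samples})
        for pair in itertools.combinations(donors, 2):
            seen[pair] = seen.get(pair, 0) + 1
    violations = sorted(pair for pair, n in seen.items() if n > 1)
    return DesignReport(valid=not violations, violations=violations)


def concordance(sig1: GenotypeSignature, sig2: GenotypeSignature) -> float:
    """Fraction of exactly matching VAF calls over SNPs non-missing in both."""
    both = ~np.isnan(sig1.vaf) & ~np.isnan(sig2.vaf)
    n = int(both.sum())
    if n == 0:
        raise ValueError("signatures share no called SNPs")
    return float(np.mean(sig1.vaf[both] == sig2.vaf[both]))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


class AmbiguousIdentityError(RuntimeError):
    """A linked component's library fingerprint matches more than one donor."""


@dataclass
class AssignmentResult:
    assignments: dict[tuple[str, int], str]
    unassigned: list[tuple[str, int]]
    components: list[list[tuple[str, int]]]


def assign_identities(
    signatures: list[GenotypeSignature],
    plan: PoolPlan,
    min_concordance: float = MIN_CONCORDANCE,
    min_shared_snps: int = MIN_SHARED_SNPS,
) -> AssignmentResult:
    """Assign anonymous clusters to donors via concordance links + fingerprints.

    Cluster pairs from *different* libraries with concordance at or above
    ``min_concordance`` over at least ``min_shared_snps`` shared SNPs are
    linked; connected components are putative donors. A component is assigned
    the donor whose planned library set equals the component's library set
    exactly; components matching no donor uniquely are left unassigned, and a
    component whose fingerprint matches several donors (possible only if two
    donors share an identical library set) raises
    :class:`AmbiguousIdentityError`.
    """
    report = validate_design(plan)
    if not report.valid:
        raise ValueError(
            f"pool plan violates the no-repeated-pair design: {report.violations}"
        )
    keys = [(s.library, s.cluster_index) for s in signatures]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (library, cluster_index) signatures")
    uf = _UnionFind(len(signatures))
    for i, j in itertools.combinations(range(len(signatures)), 2):
        a, b = signatures[i], signatures[j]
        if a.library == b.library:
            continue
        both = ~np.isnan(a.vaf) & ~np.isnan(b.vaf)
        if int(both.sum()) < min_shared_snps:
            continue
        if np.mean(a.vaf[both] == b.vaf[both]) >= min_concordance:
            uf.union(i, j)

    comp_members: dict[int, list[int]] = {}
    for i in range(len(signatures)):
        comp_members.setdefault(uf.find(i), []).append(i)

    fingerprints = plan.donor_libraries()
    assignments: dict[tuple[str, int], str] = {}
    unassigned: list[tuple[str, int]] = []
    components = []
    for members in comp_members.values():
        comp_keys = [keys[i] for i in members]
        components.append(comp_keys)
        libs = frozenset(lib for lib, _ in comp_keys)
        matches = [d for d, fp in fingerprints.items() if fp == libs]
        if len(matches) > 1:
            # several donors share this exact library set: a lone cluster is
            # simply unresolvable (unassigned), but a multi-cluster component
            # means distinct identities were merged — a hard error
            if len(comp_keys) > 1:
                raise AmbiguousIdentityError(
                    f"component spanning libraries {sorted(libs)} matches donors {matches}"
                )
            unassigned.extend(comp_keys)
            continue
        if len(matches) == 1:
            for key in comp_keys:
                assignments[key] = matches[0]
            continue
        # no exact match: a component explainable as several donors whose
        # fingerprints tile its library set (e.g. genetically identical
        # donors whose clusters were linked) is ambiguous, not unassigned
        subsets = [d for d, fp in fingerprints.items() if fp <= libs]
        if len(subsets) >= 2 and frozenset().union(*(fingerprints[d] for d in subsets)) == libs:
            raise AmbiguousIdentityError(
                f"component spanning libraries {sorted(libs)} could be any of {sorted(subsets)}"
            )
        unassigned.extend(comp_keys)
    return AssignmentResult(
        assignments=assignments,
        unassigned=sorted(unassigned),
        components=components,
    )
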
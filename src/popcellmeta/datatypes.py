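"""Core domain containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = ("AA-NL", "L", "W-NL")
REGIONS = ("DLPFC", "STG", "AC")
DIAGNOSES = ("NCI", "MCI", "AD")

#: Phenotypes modeled with education as an extra covariate.
COGNITIVE_TRAITS = frozenset({"cog_decline", "clinical_dx"})


@dataclass(frozen=True)
class PhenotypeSet:
    """AD phenotypes for one donor, on the transformed scales used for modeling.

    cerad is coded 1=Definite AD ... 4=No AD; braak 0-6. Plaque counts are
    means of per-region SD-scaled counts. amyloid_sqrt / tangles_sqrt are
    square roots of percent-area and density. cog_decline is the negated
    person-specific slope of global cognition (higher = steeper decline).
    """

    cerad: int
    braak: int
    neuritic_plaques: float
    diffuse_plaques: float
    amyloid_sqrt: float
    tangles_sqrt: float
    clinical_dx: str
    cog_decline: float

    def __post_init__(self) -> None:
        if not 1 <= self.cerad <= 4:
            raise ValueError(f"cerad must be in 1..4, got {self.cerad}")
        if not 0 <= self.braak <= 6:
            raise ValueError(f"braak must be in 0..6, got {self.braak}")
        if self.amyloid_sqrt < 0 or self.tangles_sqrt < 0:
            raise ValueError("sqrt-scale pathology values must be nonnegative")
        if self.clinical_dx not in DIAGNOSES:
            raise ValueError(f"clinical_dx must be one of {DIAGNOSES}")


@dataclass(frozen=True)
class DonorRecord:
    """One donor: population group, demographic covariates and phenotypes."""

    donor_id: str
    group: str
    age_at_death: float
    sex: str
    pmi: float
    education: float
    phenotypes: PhenotypeSet

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if not 60 <= self.age_at_death <= 110:
            raise ValueError("age_at_death must lie in [60, 110]")
        if not 0 <= self.pmi <= 72:
            raise ValueError("pmi must lie in [0, 72]")
        if self.education < 0:
            raise ValueError("education must be nonnegative")


@dataclass
class CompositionTable:
    """Nucleus counts per subcluster for (donor, region) samples of one broad class.

    ``counts`` is indexed by a (donor_id, region) MultiIndex with one column
    per subcluster; entries are nonnegative integer nucleus counts.
    """

    counts: pd.DataFrame
    broad_class: str = "unknown"

    def __post_init__(self) -> None:
        if not isinstance(self.counts.index, pd.MultiIndex):
            raise ValueError("counts must be indexed by (donor_id, region)")
        regions = self.counts.index.get_level_values(1)
        bad = set(regions) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown regions: {sorted(bad)}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.counts.sum(axis=1) <= 0).any():
            raise ValueError("every sample must contain at least one nucleus")

    @property
    def subclusters(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def denominators(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth log-odds slope of one subcluster on one phenotype, per group."""

    subcluster: str
    phenotype: str
    beta_per_group: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.beta_per_group) != set(GROUPS):
            raise ValueError(f"beta_per_group must give a slope for each of {GROUPS}")

    @property
    def conserved(self) -> bool:
        signs = {np.sign(b) for b in self.beta_per_group.values()}
        return len(signs) == 1 and 0.0 not in signs


@dataclass
class PoolPlan:
    """Library pooling design: each library holds exactly 3 (donor, region) samples."""

    members: dict[str, list[tuple[str, str]]]

    def __post_init__(self) -> None:
        for lib, samples in self.members.items():
            donors = [d for d, _ in samples]
            if len(samples) != 3 or len(set(donors)) != 3:
                raise ValueError(
                    f"library {lib!r} must contain exactly 3 samples from 3 "
                    f"distinct donors, got {samples}"
                )

    @property
    def libraries(self) -> list[str]:
        return list(self.members)

    def donor_libraries(self) -> dict[str, frozenset[str]]:
        """The set of libraries each donor appears in (its fingerprint)."""
        out: dict[str, set[str]] = {}
        for lib, samples in self.members.items():
            for donor, _ in samples:
                out.setdefault(donor, set()).add(lib)
        return {d: frozenset(libs) for d, libs in out.items()}


@dataclass
class GenotypeSignature:
    """Anonymous per-library genotype cluster: VAF in {0, 0.5, 1} per panel SNP.

    Missing calls are NaN. All signatures of a study share one SNP panel.
    """

    library: str
    cluster_index: int
    vaf: np.ndarray

    def __post_init__(self) -> None:
        vals = self.vaf[~np.isnan(self.vaf)]
        if not np.isin(vals, (0.0, 0.5, 1.0)).all():
            raise ValueError("VAF entries must be 0, 0.5, 1 or NaN")


def cohort_frame(cohort: list[DonorRecord]) -> pd.DataFrame:
    """Flatten a cohort to one row per donor (covariates + phenotypes)."""
    rows = []
    for d in cohort:
        p = d.phenotypes
        rows.append(
            {
                "donor_id": d.donor_id,
                "group": d.group,
                "age_at_death": d.age_at_death,
                "sex": d.sex,
                "pmi": d.pmi,
                "education": d.education,
                "cerad": p.cerad,
                "braak": p.braak,
                "neuritic_plaques": p.neuritic_plaques,
                "diffuse_plaques": p.diffuse_plaques,
                "amyloid_sqrt": p.amyloid_sqrt,
                "tangles_sqrt": p.tangles_sqrt,
                "clinical_dx": p.clinical_dx,
                "cog_decline": p.cog_decline,
            }
        )
    return pd.DataFrame(rows).set_index("donor_id")
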
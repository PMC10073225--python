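"""Synthetic two-group cohorts with planted brain- and metabolite-block effects.

The generator emulates an observational obese (n=64) vs. overweight (n=53)
cohort: per-subject streamline-count connectomes over 165 parcellated brain
regions with region volumes, a 987-column fecal-metabolite abundance table,
and age/sex/diet covariates. Group signal is planted at configurable
strength in either block:

* **brain** — every edge incident to a chosen informative region has its
  expected streamline count multiplied by ``brain_effect`` in the obese
  group (injected in fiber-count space, before any network metric);
* **metabolite** — chosen informative metabolites have their log-abundance
  mean shifted by ``metabolite_effect`` within-feature standard deviations
  in the obese group (a Cohen's d on the log scale).

With ``brain_effect=1`` and ``metabolite_effect=0`` the cohort carries no
group signal in either block and downstream classifiers should perform at
chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from braingut.connectome import FiberConnectivity

__all__ = [
    "CovariateModel",
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "read_fiber_matrices",
]


@dataclass
class CovariateModel:
    """Group-wise covariate distributions (group 0 = overweight, 1 = obese).

    Defaults reproduce the clinical composition of the cohort the analysis
    was designed around: sex (male=1) 19/53 vs 17/64, diet (American=1)
    12/53 vs 29/64, ages ~N(31.45, 10.96²) vs N(33.20, 10.25²).
    """

    p_male: tuple[float, float] = (19 / 53, 17 / 64)
    p_american_diet: tuple[float, float] = (12 / 53, 29 / 64)
    age_mean: tuple[float, float] = (31.4528, 33.203125)
    age_sd: tuple[float, float] = (10.964, 10.2457)

    def validate(self) -> None:
        for p in (*self.p_male, *self.p_american_diet):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if any(s <= 0 for s in self.age_sd):
            raise ValueError("age standard deviations must be positive")

    @classmethod
    def null(cls) -> "CovariateModel":
        """Covariates identically distributed in both groups (no group signal)."""
        return cls(
            p_male=(0.3, 0.3),
            p_american_diet=(0.35, 0.35),
            age_mean=(32.0, 32.0),
            age_sd=(10.5, 10.5),
        )


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``brain_effect`` is a multiplicative scaling of expected streamline
    counts on edges incident to informative regions (1.0 = no effect);
    ``metabolite_effect`` is a standardized mean difference (Cohen's d) on
    log-abundance (0.0 = no effect). Both are applied to the obese group.
    """

    n_obese: int = 64
    n_overweight: int = 53
    n_regions: int = 165
    n_metabolites: int = 987
    informative_brain_regions: list[int] = field(default_factory=list)
    informative_metabolites: list[int] = field(default_factory=list)
    brain_effect: float = 1.0
    metabolite_effect: float = 0.0
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int = 0
    edge_density: float = 0.35
    mean_fiber_count: float = 40.0

    def validate(self) -> None:
        for name in ("n_obese", "n_overweight", "n_regions", "n_metabolites"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.brain_effect < 0 or self.metabolite_effect < 0:
            raise ValueError("effect parameters must be >= 0")
        if not 0.0 < self.edge_density <= 1.0:
            raise ValueError("edge_density must be in (0, 1]")
        for idx in self.informative_brain_regions:
            if not 0 <= idx < self.n_regions:
                raise ValueError(f"informative brain region {idx} out of range [0, {self.n_regions})")
        for idx in self.informative_metabolites:
            if not 0 <= idx < self.n_metabolites:
                raise ValueError(f"informative metabolite {idx} out of range [0, {self.n_metabolites})")
        self.covariate_model.validate()

    @property
    def n_subjects(self) -> int:
        return self.n_obese + self.n_overweight


@dataclass
class SyntheticCohort:
    """A generated cohort: connectomes, metabolite table, covariates, labels, truth."""

    fiber_matrices: list[FiberConnectivity]
    metabolite_table: pd.DataFrame  # subjects × metabolites, nonnegative abundances
    covariates: pd.DataFrame  # age, sex, diet per subject
    labels: pd.Series  # 0 = overweight, 1 = obese
    truth: dict[str, list[str]]  # planted informative region / metabolite names
    spec: CohortSpec

    @property
    def subject_ids(self) -> list[str]:
        return list(self.metabolite_table.index)

    @property
    def region_names(self) -> list[str]:
        return list(self.fiber_matrices[0].region_names)


def _region_names(n: int) -> list[str]:
    return [f"ROI_{i + 1:03d}" for i in range(n)]


def _metabolite_names(n: int) -> list[str]:
    return [f"met_{i + 1:04d}" for i in range(n)]


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort from ``spec``. Identical seeds give bit-identical cohorts.

    Fiber counts: a shared symmetric Poisson-rate template (edges present
    with probability ``edge_density``, Gamma-distributed rates with mean
    ``mean_fiber_count``) is drawn once per cohort; each subject's counts
    are Poisson draws from the template scaled by a mild subject-level
    factor, with obese subjects' informative-region edges scaled by
    ``brain_effect`` before sampling. Metabolite log-abundances are
    Gaussian per feature with the obese-group mean of informative features
    shifted by ``metabolite_effect`` standard deviations.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    R = spec.n_regions
    regions = _region_names(R)
    met_names = _metabolite_names(spec.n_metabolites)

    # subject order: interleaved draw, then a fixed shuffle so the two
    # groups are not block-ordered in the files
    labels = np.array([1] * spec.n_obese + [0] * spec.n_overweight)
    order = rng.permutation(n)
    labels = labels[order]
    subject_ids = [f"S{i + 1:03d}" for i in range(n)]

    # --- connectome template -------------------------------------------------
    iu = np.triu_indices(R, k=1)
    present = rng.random(len(iu[0])) < spec.edge_density
    rate_upper = np.zeros(len(iu[0]))
    rate_upper[present] = rng.gamma(shape=2.0, scale=spec.mean_fiber_count / 2.0, size=present.sum())
    template = np.zeros((R, R))
    template[iu] = rate_upper
    template += template.T

    base_volume = rng.lognormal(mean=8.3, sigma=0.45, size=R)  # ~2000–10000 mm³

    informative_mask = np.zeros(R, dtype=bool)
    informative_mask[spec.informative_brain_regions] = True
    # edges incident to any informative region
    incident = informative_mask[:, None] | informative_mask[None, :]
    np.fill_diagonal(incident, False)

    fiber_matrices = []
    for i in range(n):
        subj_scale = rng.lognormal(mean=0.0, sigma=0.10)
        rates = template * subj_scale
        if labels[i] == 1 and informative_mask.any():
            rates = np.where(incident, rates * spec.brain_effect, rates)
        upper = rng.poisson(rates[iu])
        counts = np.zeros((R, R), dtype=np.int64)
        counts[iu] = upper
        counts += counts.T
        volumes = base_volume * rng.lognormal(mean=0.0, sigma=0.05, size=R)
        fiber_matrices.append(
            FiberConnectivity(counts=counts, volumes=volumes, region_names=list(regions))
        )

    # --- metabolites ---------------------------------------------------------
    mu = rng.normal(loc=10.0, scale=2.0, size=spec.n_metabolites)
    sigma = rng.uniform(0.5, 1.5, size=spec.n_metabolites)
    log_abund = rng.normal(loc=mu, scale=sigma, size=(n, spec.n_metabolites))
    if spec.informative_metabolites:
        shift = np.zeros(spec.n_metabolites)
        shift[spec.informative_metabolites] = spec.metabolite_effect
        log_abund += np.outer(labels, shift * sigma)
    metabolite_table = pd.DataFrame(np.exp(log_abund), index=subject_ids, columns=met_names)

    # --- covariates ----------------------------------------------------------
    cm = spec.covariate_model
    age = np.where(
        labels == 1,
        rng.normal(cm.age_mean[1], cm.age_sd[1], size=n),
        rng.normal(cm.age_mean[0], cm.age_sd[0], size=n),
    )
    sex = (rng.random(n) < np.where(labels == 1, cm.p_male[1], cm.p_male[0])).astype(int)
    diet = (
        rng.random(n) < np.where(labels == 1, cm.p_american_diet[1], cm.p_american_diet[0])
    ).astype(int)
    covariates = pd.DataFrame(
        {"age": age, "sex": sex, "diet": diet}, index=subject_ids
    )

    truth = {
        "brain_regions": [regions[i] for i in spec.informative_brain_regions],
        "metabolites": [met_names[i] for i in spec.informative_metabolites],
    }
    return SyntheticCohort(
        fiber_matrices=fiber_matrices,
        metabolite_table=metabolite_table,
        covariates=covariates,
        labels=pd.Series(labels, index=subject_ids, name="group"),
        truth=truth,
        spec=spec,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Write a cohort as plain TSV files.

    Layout: ``connectomes/<subject>.tsv`` (square count matrix with region
    names as header row and first column), ``volumes.tsv`` (regions ×
    subjects, mm³), ``metabolites.tsv`` (subjects × features),
    ``covariates.tsv`` (age, sex, diet, group label) and ``truth.tsv``
    (planted informative feature names).
    """
    outdir = Path(outdir)
    matdir = outdir / "connectomes"
    matdir.mkdir(parents=True, exist_ok=True)
    regions = cohort.region_names
    vol = {}
    for sid, fibers in zip(cohort.subject_ids, cohort.fiber_matrices):
        pd.DataFrame(fibers.counts, index=regions, columns=regions).to_csv(
            matdir / f"{sid}.tsv", sep="\t"
        )
        vol[sid] = fibers.volumes
    pd.DataFrame(vol, index=regions).rename_axis("region").to_csv(outdir / "volumes.tsv", sep="\t")
    cohort.metabolite_table.rename_axis("subject").to_csv(outdir / "metabolites.tsv", sep="\t")
    cov = cohort.covariates.copy()
    cov["group"] = cohort.labels
    cov.rename_axis("subject").to_csv(outdir / "covariates.tsv", sep="\t")
    rows = [("brain_region", name) for name in cohort.truth["brain_regions"]]
    rows += [("metabolite", name) for name in cohort.truth["metabolites"]]
    pd.DataFrame(rows, columns=["kind", "name"]).to_csv(outdir / "truth.tsv", sep="\t", index=False)


def read_fiber_matrices(
    matrices_dir: str | Path, volumes_path: str | Path
) -> dict[str, FiberConnectivity]:
    """Read the per-subject connectome TSVs written by :func:`write_cohort`."""
    matrices_dir = Path(matrices_dir)
    volumes = pd.read_csv(volumes_path, sep="\t", index_col=0)
    out: dict[str, FiberConnectivity] = {}
    for path in sorted(matrices_dir.glob("*.tsv")):
        sid = path.stem
        mat = pd.read_csv(path, sep="\t", index_col=0)
        if sid not in volumes.columns:
            warnings.warn(f"no volumes for subject {sid}; skipping")
            continue
        vols = volumes[sid].reindex(mat.index)
        out[sid] = FiberConnectivity(
            counts=mat.to_numpy(dtype=np.int64),
            volumes=vols.to_numpy(dtype=float),
            region_names=list(mat.index),
        )
    return out
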
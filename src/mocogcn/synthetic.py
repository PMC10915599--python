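"""Synthetic paired microbiome/exposome cohorts with known ground truth.

The generator emulates the shapes of a case-control metagenomics study
observed through two views: a compositional species table (log-normal
abundances closed to the simplex) and a binary exposome table. A planted
subset of species carries a log-scale location shift in cases, a planted
subset of exposures carries a prevalence shift, and an optional coupling
term mixes an informative exposure's value into an informative species'
log-abundance, creating cross-view dependence. Every draw is reproducible
from the seed.

Defaults mirror the study shape this package targets: 57 cases vs 50
controls, 125 species, 23 binary exposures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import CohortLabels, OmicsView, write_labels, write_view


@dataclass
class SyntheticCohort:
    species_view: OmicsView
    exposome_view: OmicsView
    labels: CohortLabels
    truth: dict

    def write(self, outdir: str | Path, delimiter: str = "\t") -> None:
        """Write species.tsv, exposome.tsv, labels.tsv and truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_view(self.species_view, outdir / "species.tsv", delimiter)
        write_view(self.exposome_view, outdir / "exposome.tsv", delimiter)
        write_labels(self.labels, outdir / "labels.tsv", delimiter)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=1))


def generate_cohort(
    n_case: int = 57,
    n_control: int = 50,
    d_species: int = 125,
    d_exposome: int = 23,
    n_inf_species: int = 10,
    n_inf_exposome: int = 3,
    species_effect: float = 2.0,
    exposure_effect: float = 0.3,
    coupling: float = 0.0,
    p0: float = 0.3,
    seed: int = 0,
) -> SyntheticCohort:
    """Draw a paired two-view cohort with planted case-control signal.

    Species: per-feature baseline mean mu_j ~ N(0,1); log-abundance
    ~ N(mu_j, 1), with informative features shifted up by
    ``species_effect`` (in within-feature SD units) in cases; rows are
    exponentiated and closed to the unit simplex. Exposures: Bernoulli
    with baseline prevalence ``p0``; informative exposures use
    ``p0 + exposure_effect`` in cases. ``coupling`` in [0,1] adds
    ``coupling * x_exposure`` to a paired informative species'
    log-abundance (exposures cycle over informative species). All-zero
    exposome rows (possible at small d) get one random exposure switched
    on so every sample has a defined direction for cosine similarity.
    """
    if min(n_case, n_control, d_species, d_exposome) <= 0:
        raise ValueError("counts must be positive")
    if n_inf_species > d_species or n_inf_exposome > d_exposome:
        raise ValueError("informative feature count exceeds feature count")
    if species_effect < 0 or exposure_effect < 0:
        raise ValueError("effects must be non-negative")
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must be in [0, 1]")
    if p0 + exposure_effect > 1:
        raise ValueError(f"case prevalence p0+effect = {p0 + exposure_effect} > 1")

    rng = np.random.default_rng(seed)
    n = n_case + n_control
    y = np.zeros(n, dtype=int)
    y[rng.permutation(n)[:n_case]] = 1
    sample_ids = [f"S{i:04d}" for i in range(n)]
    species_ids = [f"sp{j:03d}" for j in range(d_species)]
    exposome_ids = [f"ex{j:02d}" for j in range(d_exposome)]

    inf_sp = np.sort(rng.choice(d_species, n_inf_species, replace=False))
    inf_ex = np.sort(rng.choice(d_exposome, n_inf_exposome, replace=False))

    # exposome first (species may couple to it)
    prev = np.full((n, d_exposome), p0)
    prev[np.ix_(y == 1, inf_ex)] = p0 + exposure_effect
    E = (rng.random((n, d_exposome)) < prev).astype(float)
    empty = np.flatnonzero(E.sum(axis=1) == 0)
    for i in empty:
        E[i, rng.integers(d_exposome)] = 1.0

    mu = rng.normal(0.0, 1.0, size=d_species)
    logA = rng.normal(0.0, 1.0, size=(n, d_species)) + mu
    logA[np.ix_(y == 1, inf_sp)] += species_effect
    if coupling > 0 and n_inf_species and n_inf_exposome:
        for pos, ej in enumerate(inf_ex):
            sj = inf_sp[pos % n_inf_species]
            logA[:, sj] += coupling * E[:, ej]
    A = np.exp(logA)
    A /= A.sum(axis=1, keepdims=True)

    truth = {
        "informative_species": [species_ids[j] for j in inf_sp],
        "informative_exposures": [exposome_ids[j] for j in inf_ex],
        "species_effect": species_effect,
        "exposure_effect": exposure_effect,
        "coupling": coupling,
        "p0": p0,
        "seed": seed,
    }
    return SyntheticCohort(
        species_view=OmicsView("species", sample_ids, species_ids, A),
        exposome_view=OmicsView("exposome", sample_ids, exposome_ids, E),
        labels=CohortLabels(sample_ids, y),
        truth=truth,
    )


def generate_null_cohort(n: int, d_species: int = 125, d_exposome: int = 23,
                         seed: int = 0) -> SyntheticCohort:
    """Cohort with no planted signal: labels are random, effects are zero."""
    if n < 2:
        raise ValueError("need at least two samples")
    cohort = generate_cohort(
        n_case=n // 2, n_control=n - n // 2,
        d_species=d_species, d_exposome=d_exposome,
        n_inf_species=0, n_inf_exposome=0,
        species_effect=0.0, exposure_effect=0.0, coupling=0.0,
        seed=seed,
    )
    return cohort


def hide_labels(cohort: SyntheticCohort, fraction: float, seed: int = 0) -> CohortLabels:
    """Stratified random masking of a fraction of labels per class.

    The returned labels keep the true ``y`` (so pseudo-label accuracy can
    be scored afterwards) but mark masked samples as invisible to
    training via ``labeled_mask``.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    labels = cohort.labels
    rng = np.random.default_rng(seed)
    mask = np.ones(labels.n_samples, dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(labels.y == cls)
        n_hide = int(round(fraction * len(idx)))
        if n_hide >= len(idx):
            raise ValueError(f"masking would leave class {cls} empty")
        mask[rng.choice(idx, n_hide, replace=False)] = False
    return CohortLabels(list(labels.sample_ids), labels.y.copy(), mask)
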
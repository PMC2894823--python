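"""Synthetic CNV call sets with planted phenotype effects.

The generator emulates a SNP-array cohort study: a marker map with roughly
exponential spacing, per-subject CNV calls made of (a) *planted* regions —
spans carried by a Bernoulli-drawn subset of subjects, boundaries jittered
by up to two markers to mimic caller noise (the fragmentation that motivates
the merge step), and (b) sparse *background* CNVs scattered per subject and
chromosome.  The quantitative phenotype follows

    y = intercept + Σ_r β_r · state_r + Σ_c γ_c · covariate_c + ε,
    ε ~ N(0, σ²)

so the association engine should recover each planted β on the signed-dose
scale.  Genotype doses are drawn per marker under Hardy–Weinberg with a
uniform random allele frequency.  Everything flows from a single seed:
identical seeds give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from . import io_formats as iof
from .io_formats import CnvCall, GenotypeTable, PhenotypeTable, SnpMarker

__all__ = [
    "PlantedRegion",
    "SimConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_null_gwas_inputs",
    "write_fixture_bundle",
]


@dataclass(frozen=True)
class PlantedRegion:
    """A CNV region carried at a fixed frequency with a phenotype effect."""

    chromosome: str
    start_pos: int
    end_pos: int
    frequency: float
    beta: float
    #: signed-dose value → probability, e.g. {-1: 0.8, +1: 0.2}
    state_dist: tuple = ((-1, 1.0),)

    def __post_init__(self):
        if not 0.0 < self.frequency < 1.0:
            raise ConfigError(f"planted frequency must be in (0,1), got {self.frequency}")
        if self.start_pos >= self.end_pos:
            raise ConfigError("planted region start must be < end")
        total = sum(p for _, p in self.state_dist)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"state_dist probabilities must sum to 1, got {total}")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a desk-scale cohort: 500 subjects, two 1-Mb
    chromosomes with ~5 kb mean marker spacing, one planted 200-kb loss
    region at carrier frequency 0.2 with β = 0.5 on a noise-SD-1 phenotype,
    and sparse background CNVs (0.5 per subject per chromosome).  The
    planted span (~40 markers) is deliberately long relative to the ≤2-marker
    boundary jitter, so recovery tests the association machinery rather than
    the detector's inherent boundary approximation.
    """

    n_subjects: int = 500
    chromosome_lengths: tuple = (("1", 1_000_000), ("2", 1_000_000))
    snp_spacing: int = 5_000
    planted_regions: tuple = (
        PlantedRegion("1", 400_001, 600_000, frequency=0.2, beta=0.5),
    )
    background_cnv_rate: float = 0.5
    intercept: float = 25.0
    covariate_effects: tuple = (("age", 0.05), ("sex", -0.8))
    noise_sd: float = 1.0
    phenotype_name: str = "bmi"
    with_genotypes: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.background_cnv_rate < 0:
            raise ConfigError("background_cnv_rate must be >= 0")
        regions = sorted(self.planted_regions,
                         key=lambda r: (r.chromosome, r.start_pos))
        for a, b in zip(regions, regions[1:]):
            if a.chromosome == b.chromosome and b.start_pos <= a.end_pos:
                raise ConfigError(
                    f"planted regions overlap: {a.chromosome}:{a.start_pos}-{a.end_pos} "
                    f"and {b.chromosome}:{b.start_pos}-{b.end_pos}"
                )


@dataclass
class SimulatedDataset:
    """Everything the readers consume plus the ground truth that made it."""

    snp_map: list
    calls: list
    phenotypes: PhenotypeTable
    genotypes: Optional[GenotypeTable]
    truth: dict


def _simulate_snp_map(cfg: SimConfig, rng) -> list[SnpMarker]:
    markers = []
    for chrom, length in cfg.chromosome_lengths:
        pos = 0
        i = 0
        while True:
            pos += max(1, int(round(rng.exponential(cfg.snp_spacing))))
            if pos > length:
                break
            i += 1
            markers.append(SnpMarker(f"SNP_{chrom}_{i:05d}", chrom, pos))
    return markers


def _positions_by_chrom(snp_map):
    by = {}
    for m in snp_map:
        by.setdefault(m.chromosome, []).append(m.position)
    return {c: np.asarray(sorted(p)) for c, p in by.items()}


def simulate_dataset(cfg: SimConfig, seed: Optional[int] = None) -> SimulatedDataset:
    """Generate one cohort (SNP map, CNV calls, phenotypes, genotypes, truth).

    ``seed`` overrides ``cfg.seed``; all randomness flows from it.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    snp_map = _simulate_snp_map(cfg, rng)
    pos_by_chrom = _positions_by_chrom(snp_map)
    subjects = [f"S{i:04d}" for i in range(1, cfg.n_subjects + 1)]
    calls: list[CnvCall] = []
    truth_regions = []
    planted_effect = np.zeros(cfg.n_subjects)

    for region in cfg.planted_regions:
        positions = pos_by_chrom.get(region.chromosome)
        if positions is None or positions.size < 5:
            raise ConfigError(
                f"planted region chromosome {region.chromosome!r} has too few markers"
            )
        lo = int(np.searchsorted(positions, region.start_pos, side="left"))
        hi = int(np.searchsorted(positions, region.end_pos, side="right")) - 1
        if hi - lo < 4:
            raise ConfigError("planted region must span at least 5 markers")
        carrier_mask = rng.random(cfg.n_subjects) < region.frequency
        state_values = np.array([v for v, _ in region.state_dist])
        state_probs = np.array([p for _, p in region.state_dist])
        states = np.zeros(cfg.n_subjects, dtype=int)
        carrier_states = rng.choice(state_values, size=int(carrier_mask.sum()),
                                    p=state_probs)
        states[carrier_mask] = carrier_states
        # boundary jitter of at most 2 markers models caller noise
        for subj_idx in np.flatnonzero(carrier_mask):
            j_lo = int(np.clip(lo + rng.integers(-2, 3), 0, positions.size - 1))
            j_hi = int(np.clip(hi + rng.integers(-2, 3), 0, positions.size - 1))
            if j_hi <= j_lo:
                j_lo, j_hi = lo, hi
            calls.append(
                CnvCall(
                    subject_id=subjects[subj_idx],
                    chromosome=region.chromosome,
                    start_pos=int(positions[j_lo]),
                    end_pos=int(positions[j_hi]),
                    state=int(states[subj_idx]),
                    n_snps=j_hi - j_lo + 1,
                )
            )
        planted_effect += region.beta * states
        truth_regions.append(
            {
                "chromosome": region.chromosome,
                "start": region.start_pos,
                "end": region.end_pos,
                "snapped_start": int(positions[lo]),
                "snapped_end": int(positions[hi]),
                "frequency": region.frequency,
                "beta": region.beta,
                "n_carriers": int(carrier_mask.sum()),
                "carriers": [subjects[i] for i in np.flatnonzero(carrier_mask)],
                "states": {subjects[i]: int(states[i])
                           for i in np.flatnonzero(carrier_mask)},
            }
        )

    if cfg.background_cnv_rate > 0:
        for chrom, _ in cfg.chromosome_lengths:
            positions = pos_by_chrom.get(chrom)
            if positions is None or positions.size < 3:
                continue
            counts = rng.poisson(cfg.background_cnv_rate, size=cfg.n_subjects)
            for subj_idx in np.flatnonzero(counts):
                for _ in range(counts[subj_idx]):
                    span = int(rng.integers(2, 15))  # CNV length in markers
                    start_i = int(rng.integers(0, max(1, positions.size - span)))
                    end_i = min(start_i + span - 1, positions.size - 1)
                    state = int(rng.choice([-2, -1, 1, 2], p=[0.05, 0.55, 0.35, 0.05]))
                    calls.append(
                        CnvCall(
                            subject_id=subjects[subj_idx],
                            chromosome=chrom,
                            start_pos=int(positions[start_i]),
                            end_pos=int(positions[end_i]),
                            state=state,
                            n_snps=end_i - start_i + 1,
                        )
                    )

    age = np.round(rng.uniform(35, 75, cfg.n_subjects), 1)
    sex = rng.integers(1, 3, cfg.n_subjects).astype(float)
    covs = {"age": age, "sex": sex}
    y = cfg.intercept + planted_effect + rng.normal(0.0, cfg.noise_sd, cfg.n_subjects)
    for name, effect in cfg.covariate_effects:
        y = y + effect * covs[name]
    phenotypes = PhenotypeTable(
        pd.DataFrame(
            {cfg.phenotype_name: y, "age": age, "sex": sex},
            index=pd.Index(subjects, name="subject_id"),
        )
    )

    genotypes = None
    if cfg.with_genotypes:
        mafs = rng.uniform(0.05, 0.5, len(snp_map))
        doses = rng.binomial(2, mafs[:, None], size=(len(snp_map), cfg.n_subjects)).astype(float)
        missing = rng.random(doses.shape) < 0.01
        doses[missing] = np.nan
        genotypes = GenotypeTable(
            pd.DataFrame(doses,
                         index=pd.Index([m.marker_id for m in snp_map], name="marker_id"),
                         columns=subjects)
        )

    truth = {
        "seed": int(cfg.seed if seed is None else seed),
        "n_subjects": cfg.n_subjects,
        "phenotype": cfg.phenotype_name,
        "intercept": cfg.intercept,
        "covariate_effects": dict(cfg.covariate_effects),
        "noise_sd": cfg.noise_sd,
        "background_cnv_rate": cfg.background_cnv_rate,
        "planted_regions": truth_regions,
        "betas": [r["beta"] for r in truth_regions],
    }
    return SimulatedDataset(snp_map, calls, phenotypes, genotypes, truth)


def simulate_null_gwas_inputs(
    n_subjects: int,
    n_regions: int,
    seed: int,
    carrier_frequency: float = 0.1,
    phenotype_name: str = "y",
):
    """States and phenotypes with *no* association, for type-I calibration.

    Each of ``n_regions`` independent regions gets Bernoulli carriers at
    ``carrier_frequency`` with loss state −1; the phenotype is standard
    normal, independent of every state.  Returns
    ``(CnvrStateMatrix, PhenotypeTable)``.
    """
    from .cnvr_detection import CnvrStateMatrix, SubCnvr

    if not 0.0 < carrier_frequency < 1.0:
        raise ConfigError("carrier_frequency must be in (0,1)")
    rng = np.random.default_rng(seed)
    subjects = [f"S{i:04d}" for i in range(1, n_subjects + 1)]
    states = -(rng.random((n_regions, n_subjects)) < carrier_frequency).astype(float)
    regions = []
    rows = {}
    for i in range(n_regions):
        start = 1 + i * 10_000
        carriers = frozenset(s for s, v in zip(subjects, states[i]) if v != 0)
        region = SubCnvr(
            chromosome="1", start_pos=start, end_pos=start + 5_000,
            n_subjects=n_subjects,
            carrier_ids=carriers if carriers else frozenset({subjects[0]}),
            n_carriers=len(carriers),
        )
        regions.append(region)
        rows[region.region_id] = states[i]
    frame = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    frame.columns = subjects
    frame.index.name = "region_id"
    phenos = PhenotypeTable(
        pd.DataFrame({phenotype_name: rng.standard_normal(n_subjects)},
                     index=pd.Index(subjects, name="subject_id"))
    )
    return CnvrStateMatrix(frame=frame, regions=regions), phenos


BUNDLE_FILES = {
    "cnv": "cnv_calls.csv",
    "segment_summary": "segment_summary.txt",
    "phenotypes": "phenotypes.csv",
    "genotypes": "genotypes.call",
    "truth": "truth.json",
    "snp_map": "snp_map.csv",
}


def write_fixture_bundle(dataset: SimulatedDataset, directory, force: bool = False) -> dict:
    """Write one directory exercising every reader; returns {role: path}.

    Refuses to write into an existing non-empty directory unless ``force``.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise ConfigError(f"{directory} exists and is not empty (use force=True)")
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / name for k, name in BUNDLE_FILES.items()}
    iof.write_generic_cnv_csv(dataset.calls, paths["cnv"])
    iof.write_segment_summary(dataset.calls, paths["segment_summary"])
    iof.write_phenotypes(dataset.phenotypes, paths["phenotypes"])
    if dataset.genotypes is not None:
        iof.write_genotype_calls(dataset.genotypes, paths["genotypes"])
    else:
        del paths["genotypes"]
    paths["truth"].write_text(json.dumps(dataset.truth, indent=1), encoding="utf-8")
    iof.write_snp_map(dataset.snp_map, paths["snp_map"])
    return paths
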
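"""Synthetic multi-modal cohort generator with planted informative features.

Emulates the structure of an imaging-genetics case/control cohort: a
continuous "imaging" block (unit-variance normal features; informative
features get a class-dependent mean shift of ``effect_size`` standard
deviations) and an additive-coded genotype block (each SNP is a sum of two
Bernoulli minor-allele draws, so values lie in {0, 1, 2}; informative SNPs
use class-specific minor-allele frequencies separated by ``snp_effect``).

The ground-truth informative indices are returned *alongside* the dataset,
never stored inside it, so they cannot leak into the selection pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import MultiModalDataset
from .errors import ConfigurationError

#: default base minor-allele frequency for non-informative SNPs; the real
#: cohort's allele-frequency spectrum is unknown, 0.3 is a common-variant
#: frequency typical of genotyping-array content.
BASE_MAF = 0.3


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``effect_size`` is the standardized between-class mean shift on
    informative imaging features (unitless, in SD units); ``snp_effect`` is
    the between-class minor-allele-frequency shift on informative SNPs
    (probability units).
    """

    n_per_class: int = 25
    n_classes: int = 2
    d_imaging: int = 95
    d_snp: int = 916
    k_informative_imaging: int = 5
    k_informative_snp: int = 5
    effect_size: float = 1.0
    snp_effect: float = 0.25
    base_maf: float = BASE_MAF
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1 or self.n_classes < 2:
            raise ConfigurationError("need n_per_class >= 1 and n_classes >= 2")
        if self.k_informative_imaging > self.d_imaging:
            raise ConfigurationError(
                f"k_informative_imaging={self.k_informative_imaging} exceeds "
                f"d_imaging={self.d_imaging}"
            )
        if self.k_informative_snp > self.d_snp:
            raise ConfigurationError(
                f"k_informative_snp={self.k_informative_snp} exceeds d_snp={self.d_snp}"
            )
        if not 0.0 < self.base_maf < 1.0:
            raise ConfigurationError(f"base minor-allele frequency {self.base_maf} not in (0, 1)")
        top = self.base_maf + (self.n_classes - 1) * self.snp_effect
        if self.snp_effect < 0 or top > 1.0:
            raise ConfigurationError(
                f"base_maf + (n_classes-1)*snp_effect = {top} must stay within [0, 1]"
            )


@dataclass
class GroundTruth:
    """Block-local indices of the planted informative features."""

    imaging: list[int] = field(default_factory=list)
    snp: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"imaging": self.imaging, "snp": self.snp}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        return cls(imaging=list(obj["imaging"]), snp=list(obj["snp"]))


def generate_cohort(spec: CohortSpec) -> tuple[MultiModalDataset, GroundTruth]:
    """Draw one cohort; the same spec (incl. seed) is bit-reproducible."""
    rng = np.random.default_rng(spec.seed)
    n, K = spec.n_per_class, spec.n_classes
    N = n * K
    labels = np.repeat([f"class{k}" for k in range(K)], n)

    info_img = np.sort(rng.choice(spec.d_imaging, size=spec.k_informative_imaging, replace=False))
    info_snp = np.sort(rng.choice(spec.d_snp, size=spec.k_informative_snp, replace=False))

    imaging = rng.standard_normal((N, spec.d_imaging))
    for k in range(K):
        rows = slice(k * n, (k + 1) * n)
        imaging[rows, info_img] += k * spec.effect_size

    maf = np.full((K, spec.d_snp), spec.base_maf)
    for k in range(K):
        maf[k, info_snp] = spec.base_maf + k * spec.snp_effect
    snp = np.empty((N, spec.d_snp))
    for k in range(K):
        rows = slice(k * n, (k + 1) * n)
        snp[rows] = rng.binomial(2, maf[k], size=(n, spec.d_snp))

    ds = MultiModalDataset(
        X=np.hstack([imaging, snp]),
        y=labels,
        modality_blocks=[
            ("imaging", (0, spec.d_imaging)),
            ("snp", (spec.d_imaging, spec.d_imaging + spec.d_snp)),
        ],
        feature_names=[f"img_{i:04d}" for i in range(spec.d_imaging)]
        + [f"rs{i:06d}" for i in range(spec.d_snp)],
        sample_ids=[f"S{i:05d}" for i in range(N)],
        class_order=[f"class{k}" for k in range(K)],
    )
    return ds, GroundTruth(imaging=info_img.tolist(), snp=info_snp.tolist())
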
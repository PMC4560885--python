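"""Synthetic cohorts, read sets, tissue panels and brain-surface images.

The generators emulate the statistical structure of a two-group serum miRNA
biomarker study (10 controls vs 20 cases): negative-binomial sequencing
counts with per-sample library sizes, a matched array platform whose
log-effects are attenuated relative to sequencing, clinical/neuroimaging
variables with optional planted group shifts, planted miRNA-variable
correlations through a Gaussian copula on the latent expression scale,
read alignments concentrated in mature -5p/-3p windows, and 2D
surface-projection brain images with a known sulcal area fraction.

Every generator is deterministic under a fixed seed; each routes all
randomness through one :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import Precursor, ReadAlignment
from .sulcal import GrayImage


# ---------------------------------------------------------------------------
# Cohort generation

@dataclass
class CohortConfig:
    """Parameters of a synthetic two-group cohort.

    Defaults mirror the reference study design: 10 controls vs 20 cases,
    500 serum miRNA features of which 16 are differential, 2.5-fold planted
    effects, and an array platform retaining only 20% of the sequencing
    log-effect (the cross-platform attenuation seen when a hybridization
    assay re-measures sequencing hits).

    ``dispersion`` is the negative-binomial size parameter k
    (variance = mu + mu^2/k); ``planted_correlations`` is a list of
    (feature index, variable index, target Pearson R) triples realized by a
    Gaussian copula between the feature's latent expression and the
    variable.
    """

    n_control: int = 10
    n_case: int = 20
    n_features: int = 500
    n_differential: int = 16
    fold_changes: float | Sequence[float] = 2.5
    array_attenuation: float = 0.2
    dispersion: float = 5.0
    library_size_mean: float = 1e6
    library_size_sigma: float = 0.25
    array_sigma: float = 0.25
    n_variables: int = 8
    n_shifted_variables: int = 2
    variable_shift: float = 1.5
    planted_correlations: Sequence[tuple[int, int, float]] = ()
    seed: int = 42

    def validate(self) -> None:
        if self.n_control <= 0 or self.n_case <= 0:
            raise ValueError("group sizes must be positive")
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if not 0 <= self.n_differential <= self.n_features:
            raise ValueError("n_differential must be in [0, n_features]")
        folds = self.fold_vector()
        if (folds <= 0).any():
            raise ValueError("fold changes must be strictly positive")
        if not 0 < self.array_attenuation <= 1:
            raise ValueError("array_attenuation must be in (0, 1]")
        if self.dispersion <= 0 or self.library_size_mean <= 0:
            raise ValueError("dispersion and library_size_mean must be positive")
        if self.n_variables < 0:
            raise ValueError("n_variables must be non-negative")
        for f, v, r in self.planted_correlations:
            if not 0 <= f < self.n_features:
                raise ValueError(f"planted correlation references unknown feature {f}")
            if not 0 <= v < self.n_variables:
                raise ValueError(f"planted correlation references unknown variable {v}")
            if not abs(r) < 1:
                raise ValueError("planted |R| must be < 1")

    def fold_vector(self) -> np.ndarray:
        if np.isscalar(self.fold_changes):
            return np.full(self.n_differential, float(self.fold_changes))
        folds = np.asarray(self.fold_changes, dtype=float)
        if folds.shape != (self.n_differential,):
            raise ValueError("fold_changes must be scalar or length n_differential")
        return folds


def study_config(seed: int = 42, **overrides) -> CohortConfig:
    """A cohort mirroring the reference study: 10 vs 20 subjects, 500
    features, 16 differential miRNAs (13 up, 3 down), array attenuation 0.2.
    """
    cfg = CohortConfig(
        fold_changes=tuple([2.5] * 13 + [0.4] * 3),
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class TruthRecord:
    """Ground truth of one synthetic dataset."""

    differential: dict[str, float] = field(default_factory=dict)  # id -> fold
    correlations: list[tuple[str, str, float]] = field(default_factory=list)
    sulcal_fraction: float | None = None
    mature_fraction: float | None = None

    @property
    def directions(self) -> dict[str, int]:
        return {k: (1 if f > 1 else -1) for k, f in self.differential.items()}

    def to_dict(self) -> dict:
        return {
            "differential": self.differential,
            "correlations": [list(c) for c in self.correlations],
            "sulcal_fraction": self.sulcal_fraction,
            "mature_fraction": self.mature_fraction,
        }


@dataclass
class SyntheticCohort:
    subjects: pd.DataFrame
    seq_counts: pd.DataFrame
    array_intensity: pd.DataFrame
    truth: TruthRecord
    variable_classes: dict[str, str]


def _copula_attenuation(dispersion: float) -> float:
    """Pearson correlation between a standard normal z and the gamma mixing
    variable G = F_gamma^{-1}(Phi(z)) / k it drives.

    Planting a correlation through the copula attenuates the realized
    Pearson R by this factor; the generator divides it out so planted
    correlations hold in expectation on the expression scale.
    """
    # Gauss-Hermite quadrature (probabilists') for E[z * q(z)]; the upper
    # tail goes through isf/sf to avoid cdf saturation at extreme nodes.
    x, w = np.polynomial.hermite_e.hermegauss(101)
    w = w / np.sqrt(2 * np.pi)
    q = np.where(
        x <= 0,
        stats.gamma.ppf(stats.norm.cdf(x), a=dispersion),
        stats.gamma.isf(stats.norm.sf(x), a=dispersion),
    ) / dispersion
    cov = float((w * x * q).sum())  # E[zq] - E[z]E[q], E[z] = 0
    return cov / np.sqrt(1.0 / dispersion)


def _variable_names(n: int) -> tuple[list[str], dict[str, str]]:
    n_drink = max(1, n // 4) if n >= 4 else 0
    n_img = (n - n_drink) // 2
    n_clin = n - n_drink - n_img
    names, classes = [], {}
    for i in range(n_clin):
        name = f"clin_{i:02d}"
        names.append(name)
        classes[name] = "clinical"
    for i in range(n_img):
        name = f"img_{i:02d}"
        names.append(name)
        classes[name] = "region"
    for i in range(n_drink):
        name = f"drink_{i:02d}"
        names.append(name)
        classes[name] = "drinking"
    return names, classes


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate subject table, sequencing counts, array intensities and truth.

    Counts are gamma-Poisson (negative binomial) with per-sample log-normal
    library sizes.  Case-group differential features carry the configured
    multiplicative fold change; array intensities are log-normal with
    log-effect equal to ``array_attenuation`` times the sequencing
    log-effect.  Planted miRNA-variable correlations are realized through a
    shared standard-normal latent per sample.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_ctrl, n_case = config.n_control, config.n_case
    n = n_ctrl + n_case
    nf = config.n_features
    k = config.dispersion

    feature_ids = [f"mir-sim-{j:04d}" for j in range(nf)]
    sample_ids = [f"ctrl-{i:02d}" for i in range(n_ctrl)] + [
        f"aud-{i:02d}" for i in range(n_case)
    ]
    case = np.r_[np.zeros(n_ctrl), np.ones(n_case)]

    # Baseline composition: log-normal relative abundances.
    log_abund = rng.normal(0.0, 2.0, size=nf)
    props = np.exp(log_abund)
    props /= props.sum()

    diff_idx = rng.choice(nf, size=config.n_differential, replace=False)
    folds = config.fold_vector()
    lfc = np.zeros(nf)
    lfc[diff_idx] = np.log2(folds)

    lib = rng.lognormal(
        mean=np.log(config.library_size_mean) - 0.5 * config.library_size_sigma**2,
        sigma=config.library_size_sigma,
        size=n,
    )

    # Latent normals drive the gamma mixing variables (copula marginal
    # preservation: G = F_gamma^{-1}(Phi(z)) has mean 1, var 1/k).
    z = rng.standard_normal((n, nf))
    gamma_mix = stats.gamma.ppf(stats.norm.cdf(z), a=k) / k
    mean = lib[:, None] * props[None, :] * 2.0 ** (case[:, None] * lfc[None, :])
    counts = rng.poisson(mean * gamma_mix).astype(np.int64)

    # Array platform: log-normal intensities, attenuated log-effects.
    base_log2 = log_abund / np.log(2) + 10.0
    arr_log2 = (
        base_log2[None, :]
        + config.array_attenuation * case[:, None] * lfc[None, :]
        + rng.normal(0.0, config.array_sigma, size=(n, nf))
    )
    intensity = 2.0**arr_log2

    # Clinical / imaging / drinking variables.
    var_names, var_classes = _variable_names(config.n_variables)
    planted_by_var: dict[int, tuple[int, float]] = {
        v: (f, r) for f, v, r in config.planted_correlations
    }
    variables = {}
    shiftable = [i for i, v in enumerate(var_names) if var_classes[v] != "drinking"]
    shifted = set(shiftable[: config.n_shifted_variables])
    atten = _copula_attenuation(k)
    for vi, vname in enumerate(var_names):
        eps = rng.standard_normal(n)
        if vi in planted_by_var:
            fidx, r = planted_by_var[vi]
            # Divide out the copula attenuation so the realized Pearson R on
            # the expression scale matches the target in expectation.
            a = min(r / atten, 0.999) if r >= 0 else max(r / atten, -0.999)
            vals = a * z[:, fidx] + np.sqrt(1 - a**2) * eps
        else:
            vals = eps
        if vi in shifted:
            vals = vals + config.variable_shift * case
        if var_classes[vname] == "drinking":
            # Consumption indices exist only for cases.
            vals = np.where(case == 1, 5.0 + vals, np.nan)
        variables[vname] = vals

    subjects = pd.DataFrame(
        {"subject": sample_ids, "group": np.where(case == 1, "AUD", "control"), **variables}
    ).set_index("subject")

    truth = TruthRecord(
        differential={feature_ids[j]: float(f) for j, f in zip(diff_idx, folds)},
        correlations=[
            (feature_ids[f], var_names[v], float(r))
            for f, v, r in config.planted_correlations
        ],
    )
    seq = pd.DataFrame(counts.T, index=pd.Index(feature_ids, name="feature"), columns=sample_ids)
    arr = pd.DataFrame(intensity.T, index=pd.Index(feature_ids, name="feature"), columns=sample_ids)
    return SyntheticCohort(
        subjects=subjects, seq_counts=seq, array_intensity=arr,
        truth=truth, variable_classes=var_classes,
    )


# ---------------------------------------------------------------------------
# Read / annotation generation

def generate_annotation(
    n_precursors: int = 50,
    precursor_length: int = 120,
    mature_length: int = 24,
    mature_offset: int = 15,
    gap: int = 200,
    chrom: str = "chrS",
    seed: int = 0,
) -> list[Precursor]:
    """Synthetic hairpin annotation: equally sized precursors on one contig,
    random strands, with -5p/-3p arms at mirrored offsets from the ends."""
    if 2 * (mature_offset + mature_length) > precursor_length:
        raise ValueError("mature arms do not fit in the precursor")
    rng = np.random.default_rng(seed)
    out = []
    pos = 1000
    for i in range(n_precursors):
        start, end = pos, pos + precursor_length
        left = (start + mature_offset, start + mature_offset + mature_length)
        right = (end - mature_offset - mature_length, end - mature_offset)
        strand = "+" if rng.random() < 0.5 else "-"
        m5, m3 = (left, right) if strand == "+" else (right, left)
        out.append(
            Precursor(
                precursor_id=f"mir-sim-{i:04d}", chrom=chrom, start=start, end=end,
                strand=strand, mature5p=m5, mature3p=m3,
            )
        )
        pos = end + gap
    return out


def generate_reads(
    annotation: Sequence[Precursor],
    mature_fraction: float,
    n_reads: int,
    seed: int = 0,
    read_length: int = 22,
) -> list[ReadAlignment]:
    """Place reads on precursors: with probability ``mature_fraction`` a read
    lies wholly within a uniformly chosen mature arm; otherwise its start is
    uniform over the precursor span.  Read strand follows the precursor."""
    if not 0 <= mature_fraction <= 1:
        raise ValueError("mature_fraction must be in [0, 1]")
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    if not annotation:
        raise ValueError("annotation must be non-empty")
    for p in annotation:
        if p.mature5p is None and p.mature3p is None:
            raise ValueError(f"{p.precursor_id}: no mature interval")
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        prec = annotation[rng.integers(len(annotation))]
        if rng.random() < mature_fraction:
            arms = [iv for iv in (prec.mature5p, prec.mature3p) if iv is not None]
            a, b = arms[rng.integers(len(arms))]
            length = min(read_length, b - a)
            start = int(rng.integers(a, b - length + 1))
        else:
            length = min(read_length, prec.end - prec.start)
            start = int(rng.integers(prec.start, prec.end - length + 1))
        reads.append(
            ReadAlignment(
                chrom=prec.chrom, start=start, end=start + length,
                strand=prec.strand, name=f"read-{i}",
            )
        )
    return reads


# ---------------------------------------------------------------------------
# Tissue panel

def generate_tissue_panel(
    n_features: int = 40,
    tissues: Sequence[str] = (
        "brain", "muscle", "lung", "heart", "kidney", "thymus", "pancreas",
        "fat", "stomach", "testes", "liver", "skin", "spleen",
        "large_intestine", "small_intestine",
    ),
    n_brain_enriched: int = 5,
    enrichment_fold: float = 10.0,
    noise_sigma: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Counts for a multi-tissue panel with a planted brain-enriched subset."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=6.0, sigma=1.0, size=n_features)
    mat = base[:, None] * rng.lognormal(0.0, noise_sigma, size=(n_features, len(tissues)))
    enriched_idx = rng.choice(n_features, size=n_brain_enriched, replace=False)
    brain_col = list(tissues).index("brain")
    mat[enriched_idx, brain_col] *= enrichment_fold
    ids = [f"mir-tis-{i:03d}" for i in range(n_features)]
    df = pd.DataFrame(mat, index=pd.Index(ids, name="feature"), columns=list(tissues))
    return df, [ids[i] for i in enriched_idx]


# ---------------------------------------------------------------------------
# Brain-surface images

# Scene intensity levels: background is near-zero after skull stripping,
# sulcal shadows are dark, the gyral surface is bright.  The wide
# sulcus-gyrus separation keeps the moment-preserving threshold above the
# noise-broadened sulcal band.
_BACKGROUND, _SULCUS, _GYRUS = 2, 50, 220


def generate_brain_image(
    height: int,
    width: int,
    sulcal_fraction_true: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[GrayImage, TruthRecord]:
    """A skull-stripped surface projection: bright gyral "brain" ellipse,
    darker curvilinear sulci occupying exactly ``sulcal_fraction_true`` of
    the brain region, near-zero background.

    The image mask covers the whole frame (the field of view after skull
    stripping) so the background is part of the intensity histogram; the
    brain and sulcus regions are recorded in the TruthRecord-adjacent
    arrays returned on the image object (`brain_mask`) and the truth record
    (`sulcal_fraction`).
    """
    if height < 32 or width < 32:
        raise ValueError("image must be at least 32x32")
    if not 0 < sulcal_fraction_true < 1:
        raise ValueError("sulcal_fraction_true must be in (0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2, (width - 1) / 2
    # Ellipse < half the frame so the background stays the modal level.
    brain = ((yy - cy) / (0.36 * height)) ** 2 + ((xx - cx) / (0.36 * width)) ** 2 <= 1.0
    n_brain = int(brain.sum())
    target = int(round(sulcal_fraction_true * n_brain))
    target = max(1, min(target, n_brain - 1))

    sulci = np.zeros_like(brain)
    guard = 0
    while sulci.sum() < target and guard < 1000:
        guard += 1
        y0 = rng.uniform(0.2, 0.8) * height
        amp = rng.uniform(0.02, 0.08) * height
        freq = rng.uniform(1.0, 3.0)
        phase = rng.uniform(0, 2 * np.pi)
        thickness = 1.0
        curve = y0 + amp * np.sin(2 * np.pi * freq * xx / width + phase)
        stroke = np.abs(yy - curve) <= thickness
        sulci |= stroke & brain
    excess = int(sulci.sum()) - target
    if excess > 0:
        flat = np.flatnonzero(sulci)
        drop = rng.choice(flat, size=excess, replace=False)
        sulci.flat[drop] = False

    img = np.full((height, width), float(_BACKGROUND))
    img[brain] = _GYRUS
    img[sulci] = _SULCUS
    if noise_sd > 0:
        # Skull stripping zeroes the background, so acquisition noise lives
        # only on the reconstructed surface.
        noise = rng.normal(0.0, noise_sd, size=img.shape)
        img[brain] += noise[brain]
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    gray = GrayImage(pixels=pixels, mask=np.ones_like(brain), brain_mask=brain)
    truth = TruthRecord(sulcal_fraction=target / n_brain)
    return gray, truth
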
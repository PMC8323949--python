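"""Synthetic single-cell and bulk cohorts with a planted ASC -> CAF transition.

The generator encodes the biology the analysis is meant to recover: a latent
transition coordinate t in [0, 1] per mesenchymal cell, an adipose-derived
stromal-cell (ASC) program whose expression falls with t, a CAF program that
rises with t (with COL11A1 the last gene to switch on), transient
mid-transition genes (SFRP4/RARRES1-like) peaking at intermediate t, constant
pan-fibroblast markers, plus pericyte and epithelial compartments expressing
their own constant programs.  Counts are negative-binomial around
``library_size x amplitude x shape(t)``.

Response shapes are logistic in t for monotone programs and a Gaussian bump
for transient ones; the forms are the package's own choice, with midpoints,
steepness and bump width exposed on :class:`TransitionSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrix import ExpressionMatrix, write_counts

__all__ = [
    "GeneProgram",
    "TransitionSpec",
    "SampleProfile",
    "TDistribution",
    "make_transition_spec",
    "generate_sample",
    "generate_cohort",
    "generate_bulk_cohort",
    "analytic_mean",
]

ASC_GENES = (
    "APOD",
    "CFD",
    "MGP",
    "PTGDS",
    "CXCL12",
    "DPT",
    "C7",
    "ADH1B",
    "ABCA8",
)
CAF_GENES = (
    "COL11A1",
    "THBS2",
    "INHBA",
    "COL10A1",
    "MFAP5",
    "CTHRC1",
    "COL12A1",
    "FN1",
    "AEBP1",
    "MMP11",
)
TRANSIENT_GENES = ("SFRP4", "RARRES1")
PAN_FIBRO_GENES = ("LUM", "DCN", "FBLN1", "COL1A2", "MMP2", "SFRP2")
PERICYTE_GENES = ("RGS5", "ACTA2", "PDGFRB", "ADIRF")
EPITHELIAL_GENES = ("EPCAM", "KRT8", "KRT18", "KRT19")

#: ambient relative expression of every program gene, inside or outside its
#: own compartment: "off" genes yield rare stray counts with no structure,
#: so marker-based typing and association rankings see a clean null
AMBIENT = 0.005


@dataclass(frozen=True)
class GeneProgram:
    """A named set of genes sharing one response curve in t.

    ``shape`` is one of decreasing | increasing | bell | constant; monotone
    shapes are logistic with parameters ``t0`` (midpoint) and ``steepness``;
    ``bell`` is a Gaussian bump at ``peak`` with width ``width``.
    ``amplitude`` scales the mean expression of every gene in the program.
    """

    name: str
    genes: tuple[str, ...]
    shape: str
    amplitude: float = 1.0
    t0: float = 0.5
    steepness: float = 8.0
    peak: float = 0.5
    width: float = 0.15
    compartment: str = "fibroblast"

    def __post_init__(self) -> None:
        if self.shape not in ("decreasing", "increasing", "bell", "constant"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.steepness <= 0 or self.width <= 0:
            raise ValueError("steepness and width must be positive")

    def response(self, t: np.ndarray, t0: float | None = None) -> np.ndarray:
        """Relative response in [0, 1] as a function of t."""
        t = np.asarray(t, dtype=float)
        t0 = self.t0 if t0 is None else t0
        if self.shape == "constant":
            return np.ones_like(t)
        if self.shape == "increasing":
            return 1.0 / (1.0 + np.exp(-self.steepness * (t - t0)))
        if self.shape == "decreasing":
            return 1.0 / (1.0 + np.exp(self.steepness * (t - t0)))
        return np.exp(-((t - self.peak) ** 2) / (2.0 * self.width**2))


@dataclass(frozen=True)
class TransitionSpec:
    """Full generative description of a cohort.

    ``col11a1_delay`` shifts COL11A1's logistic midpoint to the right of the
    other CAF genes, making it the last gene to switch on.
    """

    programs: tuple[GeneProgram, ...]
    n_background_genes: int = 60
    dispersion: float = 0.3
    #: log-normal per-cell depth factor multiplying amplitude x shape(t);
    #: the median factor of 12 yields cell totals of a few thousand counts
    library_size_log_mean: float = np.log(12.0)
    library_size_log_sd: float = 0.25
    col11a1_delay: float = 0.25
    #: per-gene multipliers on top of the program amplitude: APOD and CFD are
    #: among the most abundant ASC transcripts, and COL11A1 is one of the most
    #: strongly induced collagens of the differentiated CAF state
    gene_amplitude: tuple[tuple[str, float], ...] = (
        ("APOD", 2.5),
        ("CFD", 1.8),
        ("COL11A1", 2.0),
    )

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.library_size_log_sd < 0:
            raise ValueError("library size scale must be >= 0")
        seen: set[str] = set()
        for prog in self.programs:
            for g in prog.genes:
                if g in seen:
                    raise ValueError(f"gene {g!r} appears in more than one program")
                seen.add(g)

    @property
    def background_genes(self) -> tuple[str, ...]:
        return tuple(f"BG{i:04d}" for i in range(1, self.n_background_genes + 1))

    @property
    def all_genes(self) -> tuple[str, ...]:
        out: list[str] = []
        for prog in self.programs:
            out.extend(prog.genes)
        out.extend(self.background_genes)
        return tuple(out)

    def background_amplitude(self, i: int) -> float:
        """Deterministic log-spaced amplitudes so background genes span the
        realistic range from near-silent to abundant while carrying no t
        signal."""
        n = max(self.n_background_genes, 1)
        return float(np.exp(np.linspace(np.log(0.01), np.log(4.0), n))[i])

    def effective_t0(self, program: GeneProgram, gene: str) -> float:
        if program.name == "CAF" and gene == "COL11A1":
            return program.t0 + self.col11a1_delay
        return program.t0

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_background_genes": self.n_background_genes,
            "dispersion": self.dispersion,
            "library_size_log_mean": float(self.library_size_log_mean),
            "library_size_log_sd": float(self.library_size_log_sd),
            "col11a1_delay": self.col11a1_delay,
            "programs": [
                {
                    "name": p.name,
                    "genes": list(p.genes),
                    "shape": p.shape,
                    "amplitude": p.amplitude,
                    "t0": p.t0,
                    "steepness": p.steepness,
                    "peak": p.peak,
                    "width": p.width,
                    "compartment": p.compartment,
                }
                for p in self.programs
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


_SPEC_FIELDS = {
    "n_background_genes",
    "dispersion",
    "library_size_log_mean",
    "library_size_log_sd",
    "col11a1_delay",
    "asc_amplitude",
    "caf_amplitude",
    "transient_amplitude",
    "pan_fibro_amplitude",
    "asc_t0",
    "caf_t0",
    "steepness",
}


def make_transition_spec(overrides: dict | None = None) -> TransitionSpec:
    """Build the default transition spec, optionally overriding parameters.

    Defaults plant the canonical ASC and CAF gene lists, transient SFRP4/
    RARRES1, the pan-fibroblast markers, and pericyte/epithelial compartment
    programs.  Unknown override keys raise a configuration error.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - _SPEC_FIELDS
    if unknown:
        raise KeyError(f"unknown override key(s): {sorted(unknown)}")
    asc_t0 = overrides.pop("asc_t0", 0.35)
    caf_t0 = overrides.pop("caf_t0", 0.55)
    steep = overrides.pop("steepness", 8.0)
    amp = {
        "ASC": overrides.pop("asc_amplitude", 12.0),
        "CAF": overrides.pop("caf_amplitude", 12.0),
        "TRANSIENT": overrides.pop("transient_amplitude", 8.0),
        "PAN_FIBRO": overrides.pop("pan_fibro_amplitude", 20.0),
    }
    programs = (
        GeneProgram(
            name="ASC",
            genes=ASC_GENES,
            shape="decreasing",
            amplitude=amp["ASC"],
            t0=asc_t0,
            steepness=steep,
        ),
        GeneProgram(
            name="CAF",
            genes=CAF_GENES,
            shape="increasing",
            amplitude=amp["CAF"],
            t0=caf_t0,
            steepness=steep,
        ),
        GeneProgram(
            name="TRANSIENT",
            genes=TRANSIENT_GENES,
            shape="bell",
            amplitude=amp["TRANSIENT"],
            peak=0.5,
            width=0.15,
        ),
        GeneProgram(
            name="PAN_FIBRO",
            genes=PAN_FIBRO_GENES,
            shape="constant",
            amplitude=amp["PAN_FIBRO"],
        ),
        GeneProgram(
            name="PERICYTE",
            genes=PERICYTE_GENES,
            shape="constant",
            amplitude=15.0,
            compartment="pericyte",
        ),
        GeneProgram(
            name="EPITHELIAL",
            genes=EPITHELIAL_GENES,
            shape="constant",
            amplitude=15.0,
            compartment="epithelial",
        ),
    )
    return TransitionSpec(programs=programs, **overrides)


@dataclass(frozen=True)
class TDistribution:
    """Distribution of the latent coordinate t for one sample's fibroblasts.

    ``kind`` is point | normal | uniform: a point mass at ``mean``; a normal
    with ``mean``/``sd`` truncated (clipped) to [0, 1]; or a uniform on
    [``low``, ``high``].
    """

    kind: str = "point"
    mean: float = 0.0
    sd: float = 0.05
    low: float = 0.0
    high: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("point", "normal", "uniform"):
            raise ValueError(f"unknown t distribution kind {self.kind!r}")
        if self.kind == "normal" and self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not (0.0 <= self.low <= self.high <= 1.0):
            raise ValueError("uniform bounds must satisfy 0 <= low <= high <= 1")
        if self.kind in ("point", "normal") and not 0.0 <= self.mean <= 1.0:
            raise ValueError("mean must lie in [0, 1]")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "point":
            return np.full(n, self.mean)
        if self.kind == "normal":
            return np.clip(rng.normal(self.mean, self.sd, size=n), 0.0, 1.0)
        return rng.uniform(self.low, self.high, size=n)


@dataclass(frozen=True)
class SampleProfile:
    """Cell counts per compartment and the t distribution of one sample."""

    sample: str
    n_fibroblasts: int = 300
    n_pericytes: int = 80
    n_epithelial: int = 80
    t_distribution: TDistribution = field(default_factory=TDistribution)
    modality: str = "UMI"

    def __post_init__(self) -> None:
        for n in (self.n_fibroblasts, self.n_pericytes, self.n_epithelial):
            if n < 0:
                raise ValueError("cell counts must be >= 0")

    @property
    def n_cells(self) -> int:
        return self.n_fibroblasts + self.n_pericytes + self.n_epithelial


def analytic_mean(
    spec: TransitionSpec, gene: str, t: np.ndarray, compartment: str = "fibroblast"
) -> np.ndarray:
    """Expected count of ``gene`` at coordinate t for an average library.

    This is the closed-form mean curve the negative-binomial draws are
    centred on: mean depth factor x amplitude x shape(t).
    """
    lib = float(
        np.exp(spec.library_size_log_mean + spec.library_size_log_sd**2 / 2.0)
    )
    return lib * _relative_raw(spec, gene, np.asarray(t, dtype=float), compartment)


def _relative_raw(
    spec: TransitionSpec, gene: str, t: np.ndarray, compartment: str
) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    boost = dict(spec.gene_amplitude).get(gene, 1.0)
    for prog in spec.programs:
        if gene in prog.genes:
            if prog.compartment != compartment:
                # marker of another compartment: ambient level only
                return np.full_like(t, AMBIENT)
            if prog.compartment != "fibroblast":
                return np.full_like(t, AMBIENT + prog.amplitude * boost)
            t0 = spec.effective_t0(prog, gene)
            return AMBIENT + prog.amplitude * boost * prog.response(t, t0=t0)
    if gene in spec.background_genes:
        i = spec.background_genes.index(gene)
        return np.full_like(t, spec.background_amplitude(i))
    raise KeyError(f"gene {gene!r} not in spec")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, disp: float) -> np.ndarray:
    """Negative-binomial via gamma-Poisson with Var = m + disp * m^2."""
    shape = 1.0 / disp
    lam = rng.gamma(shape, mean * disp)
    return rng.poisson(lam).astype(float)


def generate_sample(
    spec: TransitionSpec, profile: SampleProfile, seed: int
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate one sample; returns the count matrix and its ground truth.

    The truth table has one row per cell: cell id, sample, compartment and the
    latent t (NaN for non-fibroblast compartments).
    """
    if profile.n_cells == 0:
        raise ValueError("profile has no cells")
    rng = np.random.default_rng(seed)
    genes = spec.all_genes
    compartments = (
        ["fibroblast"] * profile.n_fibroblasts
        + ["pericyte"] * profile.n_pericytes
        + ["epithelial"] * profile.n_epithelial
    )
    n_cells = profile.n_cells
    t = np.full(n_cells, np.nan)
    t[: profile.n_fibroblasts] = profile.t_distribution.draw(
        profile.n_fibroblasts, rng
    )
    lib = np.exp(
        rng.normal(spec.library_size_log_mean, spec.library_size_log_sd, n_cells)
    )
    counts = np.zeros((len(genes), n_cells))
    for comp in ("fibroblast", "pericyte", "epithelial"):
        cols = np.asarray([c == comp for c in compartments])
        if not cols.any():
            continue
        t_comp = np.where(np.isnan(t[cols]), 0.0, t[cols])
        for i, gene in enumerate(genes):
            mean = lib[cols] * _relative_raw(spec, gene, t_comp, comp)
            counts[i, cols] = _nb_draw(rng, mean, spec.dispersion)
    cells = pd.Index([f"{profile.sample}_c{j:05d}" for j in range(n_cells)])
    truth = pd.DataFrame(
        {
            "cell": cells,
            "sample": profile.sample,
            "compartment": compartments,
            "t": t,
        }
    )
    matrix = ExpressionMatrix(
        counts=counts,
        genes=pd.Index(genes),
        cells=cells,
        sample=profile.sample,
        modality=profile.modality,
    )
    return matrix, truth


def generate_cohort(
    spec: TransitionSpec, profiles: list[SampleProfile], seed: int
) -> list[tuple[ExpressionMatrix, pd.DataFrame]]:
    """Simulate one matrix per profile with per-sample seeds derived from the
    master seed."""
    if not profiles:
        raise ValueError("need at least one profile")
    ids = [p.sample for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    seq = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seq.spawn(len(profiles))]
    return [
        generate_sample(spec, profile, child)
        for profile, child in zip(profiles, child_seeds)
    ]


def write_cohort(
    cohort: list[tuple[ExpressionMatrix, pd.DataFrame]],
    out_dir: str | Path,
    spec: TransitionSpec | None = None,
) -> None:
    """Write each sample as Matrix Market triplet + sidecars, the pooled
    ground truth as TSV, and the spec as YAML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truths = []
    for matrix, truth in cohort:
        write_counts(matrix, out_dir / matrix.sample, format="mtx")
        truths.append(truth)
    pd.concat(truths, ignore_index=True).to_csv(
        out_dir / "ground_truth.tsv", sep="\t", index=False
    )
    if spec is not None:
        spec.to_yaml(out_dir / "spec.yaml")


def normal_profile(
    sample: str, n_fibroblasts: int = 300, n_pericytes: int = 80,
    n_epithelial: int = 80,
) -> SampleProfile:
    """Preset for a normal sample: fibroblasts at t ~ 0 with small jitter."""
    return SampleProfile(
        sample=sample,
        n_fibroblasts=n_fibroblasts,
        n_pericytes=n_pericytes,
        n_epithelial=n_epithelial,
        t_distribution=TDistribution(kind="normal", mean=0.0, sd=0.03),
    )


def stage_profile(
    sample: str,
    mean_t: float,
    half_width: float = 0.3,
    n_fibroblasts: int = 400,
    n_pericytes: int = 100,
    n_epithelial: int = 80,
) -> SampleProfile:
    """Preset for a tumor sample at a given transition stage.

    Fibroblast t is uniform on a window around ``mean_t`` (clipped to [0, 1]):
    tumor samples are mixtures of cells spanning a range of transition states,
    not a single stage.  The window narrows near the endpoints — samples that
    have barely started, or essentially completed, the transition are
    dominated by homogeneous pre- or post-transition fibroblasts.
    """
    hw = min(half_width, mean_t + 0.05, (1.0 - mean_t) + 0.05)
    return SampleProfile(
        sample=sample,
        n_fibroblasts=n_fibroblasts,
        n_pericytes=n_pericytes,
        n_epithelial=n_epithelial,
        t_distribution=TDistribution(
            kind="uniform",
            low=max(0.0, mean_t - hw),
            high=min(1.0, mean_t + hw),
        ),
    )


# -- bulk cohorts for the pan-cancer screen -------------------------------

PLANTED_LNCRNA = "LNC-CAF1"


def generate_bulk_cohort(
    spec: TransitionSpec,
    n_types: int = 6,
    caf_positive_fraction: float = 0.5,
    n_samples_per_type: int = 150,
    n_ncrna: int = 40,
    seed: int = 0,
) -> list[ExpressionMatrix]:
    """Simulate per-"cancer-type" bulk count tables for the ncRNA screen.

    Every type carries a per-sample "stromal content" factor that co-scales
    COL11A1 together with a block of stromal background genes, so the
    COL11A1 ranking is informative in every type.  CAF-positive types add a
    stronger log-normal CAF-abundance factor that co-scales COL11A1,
    THBS2/INHBA and one planted lncRNA-like gene (``LNC-CAF1``); in negative
    types those genes carry no shared signal, so the stromal block crowds them
    out of the top ranks.  A slice of background genes is zero-inflated past
    50 % of samples so the zero-count filter has something to remove.  Gene
    biotypes (coding / lncRNA / miRNA) ride along as annotation.
    """
    if n_types < 2:
        raise ValueError("n_types must be >= 2")
    if not 0.0 <= caf_positive_fraction <= 1.0:
        raise ValueError("caf_positive_fraction must be in [0, 1]")
    if n_samples_per_type < 2:
        raise ValueError("need >= 2 samples per type (correlation undefined)")
    rng = np.random.default_rng(seed)
    n_positive = int(round(n_types * caf_positive_fraction))
    coding = [g for p in spec.programs for g in p.genes] + list(
        spec.background_genes
    )
    lnc = [PLANTED_LNCRNA] + [f"LNC{i:04d}" for i in range(1, n_ncrna // 2 + 1)]
    mir = [f"MIR{i:04d}" for i in range(1, n_ncrna - n_ncrna // 2 + 1)]
    genes = pd.Index(coding + lnc + mir)
    biotype = pd.DataFrame(
        {
            "biotype": ["coding"] * len(coding)
            + ["lncRNA"] * len(lnc)
            + ["miRNA"] * len(mir)
        },
        index=genes,
    )
    base_mean = {}
    for g in coding:
        base_mean[g] = float(_relative_raw(spec, g, np.array([0.5]), "fibroblast")[0]) * 40.0
    for g in lnc + mir:
        base_mean[g] = float(rng.uniform(3.0, 30.0))
    caf_driven = {"COL11A1", "THBS2", "INHBA", PLANTED_LNCRNA}
    background = list(spec.background_genes)
    stromal = set(background[: (2 * len(background)) // 3])
    # zero-inflate some of the remaining background genes past the filter bound
    free = [g for g in background if g not in stromal]
    zi_genes = set(free[:: max(len(free) // 6, 1)])
    cohort = []
    for k in range(n_types):
        positive = k < n_positive
        counts = np.zeros((len(genes), n_samples_per_type))
        stromal_factor = np.exp(rng.normal(0.0, 0.5, n_samples_per_type))
        caf_factor = np.exp(rng.normal(0.0, 0.8, n_samples_per_type))
        for i, g in enumerate(genes):
            mean = np.full(n_samples_per_type, base_mean[g])
            if g in stromal or g == "COL11A1":
                mean = mean * stromal_factor
            if g in caf_driven:
                mean = mean * (3.0 * caf_factor if positive else 1.0)
            counts[i] = _nb_draw(rng, mean, spec.dispersion)
            if g in zi_genes:
                mask = rng.random(n_samples_per_type) < 0.65
                counts[i, mask] = 0.0
        cohort.append(
            ExpressionMatrix(
                counts=counts,
                genes=genes,
                cells=pd.Index(
                    [f"TYPE{k:02d}_s{j:03d}" for j in range(n_samples_per_type)]
                ),
                sample=f"TYPE{k:02d}" + ("_pos" if positive else "_neg"),
                modality="bulk",
                gene_annotation=biotype,
            )
        )
    return cohort
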
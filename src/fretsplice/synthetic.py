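"""Ground-truth synthetic data for both pipelines.

Two generators live here:

* a forward optical model that turns a per-pixel tension field on an
  embryo-shaped object into the three acquisition channels (donor, direct
  acceptor, raw FRET), including spectral bleed-through mixing, a constant
  background and optional Poisson shot noise — built so that the index
  pipeline's printed equations are its exact algebraic inverse;
* a tiling-array scenario generator that plants intron-retention and
  exon-level misregulation into a two-genotype probe-intensity table, with
  ground-truth labels returned for recovery tests.

Tension maps to FRET through a linear entropic spring feeding the
sixth-power Förster relation:

    r(f) = r0 + f / kappa
    E(f) = 1 / (1 + (r(f) / R0)**6)

so efficiency is strictly decreasing in force and equals the zero-force
value implied by ``r0``/``R0`` at ``f = 0``.  Force-insensitive control
constructs (terminal fusion, short rigid linker, long separator) map to
constant efficiency fields.

All randomness flows from a single top-level seed through
``numpy.random.SeedSequence`` spawning: child streams are derived in a
fixed documented order (frame 0, frame 1, ... for image stacks; gene
assignment, then probe noise for array tables), so identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .fret import ChannelStack

__all__ = [
    "TensionScene",
    "ForwardModelParams",
    "SpliceScenario",
    "force_to_fret",
    "fret_to_force",
    "true_efficiency_map",
    "generate_fret_stack",
    "generate_probe_table",
]

CONSTRUCTS = ("TSMod", "5aa", "TRAF", "N-TSMod")

_COUNT_LIMIT = 2**31 - 1  # photon-count overflow guard


@dataclass
class ForwardModelParams:
    """Optics and linker parameters of the forward model.

    r0, R0
        Zero-force fluorophore separation and Förster radius (nm).  The
        defaults (6.0 and 5.4 nm) give a zero-force efficiency of ~0.35,
        in the range reported for flagelliform-linker tension modules.
    spring_constant
        Linear entropic-spring stiffness, piconewton per nanometre of
        extension (arbitrary force units are fine as long as the tension
        field uses the same ones).
    sensor_density
        Mean excitation events per cortical pixel per frame — the photon
        budget that sets the shot-noise level.
    density_cv
        Coefficient of variation of the static per-pixel sensor expression
        field (log-normal, mean-preserving, drawn once per scene from the
        scene seed).  Real embryos express the sensor unevenly; the
        expression-independence check is only meaningful when they do.
    QD
        Donor quantum yield.
    phi_ratio
        Collection-efficiency ratio phiD/phiA.  The acceptor quantum yield
        is folded into phiA, and phiA is taken as the unit of collection,
        i.e. phiD = phi_ratio and phiA = 1 — this makes the index formula
        the exact inverse of the generator.
    alpha, delta
        Acceptor / donor bleed-through fractions mixed into the raw FRET
        channel.
    background
        Constant added to every channel (counts).
    noise
        "none" for the noiseless forward model, "poisson" for shot noise.
    high_fret_E, low_fret_E
        Constant efficiencies of the short-rigid-linker ("5aa") and
        long-separator ("TRAF") control constructs.  No measured values are
        available for these controls, so they are plain configuration.
    bin_factor
        Recorded for the downstream pipeline default; the generator itself
        always emits unbinned frames.
    """

    r0: float = 6.0
    R0: float = 5.4
    spring_constant: float = 1.0
    sensor_density: float = 2000.0
    density_cv: float = 0.3
    QD: float = 0.85
    phi_ratio: float = 1.2
    alpha: float = 0.3
    delta: float = 0.15
    background: float = 100.0
    noise: str = "poisson"
    high_fret_E: float = 0.60
    low_fret_E: float = 0.12
    bin_factor: int = 1

    def __post_init__(self) -> None:
        if self.r0 <= 0 or self.R0 <= 0:
            raise ValueError("r0 and R0 must be positive lengths")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")
        if self.sensor_density <= 0:
            raise ValueError("sensor_density must be positive")
        if self.density_cv < 0:
            raise ValueError("density_cv must be non-negative")
        for name in ("QD", "alpha", "delta", "high_fret_E", "low_fret_E"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 < self.E0 < 1:
            raise ValueError("zero-force efficiency must lie strictly in (0, 1)")
        if self.noise not in ("none", "poisson"):
            raise ValueError(f"noise must be 'none' or 'poisson', got {self.noise!r}")

    @property
    def E0(self) -> float:
        """Zero-force FRET efficiency implied by r0 and R0."""
        return 1.0 / (1.0 + (self.r0 / self.R0) ** 6)


def force_to_fret(force, params: ForwardModelParams):
    """FRET efficiency of the tension module under a stretching force.

    Accepts scalars or arrays; strictly decreasing in force.
    """
    f = np.asarray(force, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("force must be non-negative (the linker cannot be compressed)")
    r = params.r0 + f / params.spring_constant
    E = 1.0 / (1.0 + (r / params.R0) ** 6)
    return float(E) if np.isscalar(force) else E


def fret_to_force(E: float, params: ForwardModelParams) -> float:
    """Inverse of :func:`force_to_fret`; E must lie in (0, E0]."""
    if not 0 < E <= params.E0:
        raise ValueError(f"E must lie in (0, E0={params.E0:.4f}], got {E}")
    r = params.R0 * ((1.0 - E) / E) ** (1.0 / 6.0)
    # E = E0 can land a round-off hair below r0; that is force zero
    return params.spring_constant * max(r - params.r0, 0.0)


@dataclass
class TensionScene:
    """An embryo-shaped object with a per-pixel tension field.

    The geometry is an ellipse whose thin cortical band carries the
    membrane-bound sensor; the sensory depression region (SDR) is a small
    box on the anterior cortex where tension is elevated (pharyngeal
    pulling).  ``sdr_box`` is (row0, row1, col0, col1), half-open, 0-based.
    """

    shape: tuple[int, int]
    embryo_mask: np.ndarray
    cortex_mask: np.ndarray
    force_field: np.ndarray
    sdr_box: tuple[int, int, int, int]
    construct: str = "TSMod"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.construct not in CONSTRUCTS:
            raise ValueError(f"construct must be one of {CONSTRUCTS}")
        self.embryo_mask = np.asarray(self.embryo_mask, dtype=bool)
        self.cortex_mask = np.asarray(self.cortex_mask, dtype=bool)
        self.force_field = np.asarray(self.force_field, dtype=np.float64)
        for name in ("embryo_mask", "cortex_mask", "force_field"):
            if getattr(self, name).shape != tuple(self.shape):
                raise ValueError(f"{name} shape does not match scene shape {self.shape}")
        if np.any(self.force_field < 0):
            raise ValueError("force_field must be non-negative")
        if np.any(self.force_field[~self.embryo_mask] != 0):
            raise ValueError("force_field must vanish outside the embryo")
        if not self.cortex_mask.any():
            raise ValueError("cortex_mask is empty — no sensor-bearing pixels")
        r0, r1, c0, c1 = self.sdr_box
        if not (0 <= r0 < r1 <= self.shape[0] and 0 <= c0 < c1 <= self.shape[1]):
            raise ValueError(f"sdr_box {self.sdr_box} out of bounds for shape {self.shape}")

    @property
    def sdr_mask(self) -> np.ndarray:
        r0, r1, c0, c1 = self.sdr_box
        m = np.zeros(self.shape, dtype=bool)
        m[r0:r1, c0:c1] = True
        return m


def make_embryo_scene(
    shape: tuple[int, int] = (80, 120),
    cortex_width: int = 3,
    force_base: float = 0.5,
    force_sdr: float = 2.0,
    sdr_size: tuple[int, int] = (14, 10),
    construct: str = "TSMod",
    seed: int = 0,
) -> TensionScene:
    """Default embryo: ellipse + cortical band + anterior high-tension box.

    The SDR box sits on the anterior (left) cortex, mimicking the sensor's
    accumulation at the future buccal cavity.  ``force_base`` acts on the
    whole embryo, ``force_sdr`` inside the SDR box.
    """
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    a, b = w * 0.42, h * 0.38  # semi-axes: anteroposterior, dorsoventral
    d = ((cc - cx) / a) ** 2 + ((rr - cy) / b) ** 2
    embryo = d <= 1.0
    inner = ((cc - cx) / (a - cortex_width)) ** 2 + ((rr - cy) / (b - cortex_width)) ** 2
    cortex = embryo & (inner > 1.0)
    # anterior pole: leftmost cortical columns
    cols = np.where(cortex.any(axis=0))[0]
    c0 = int(cols.min())
    sh, sw = sdr_size
    r0 = int(cy - sh // 2)
    box = (r0, r0 + sh, c0, c0 + sw)
    force = np.where(embryo, float(force_base), 0.0)
    force[box[0] : box[1], box[2] : box[3]] = np.where(
        embryo[box[0] : box[1], box[2] : box[3]], float(force_sdr), 0.0
    )
    return TensionScene(
        shape=shape,
        embryo_mask=embryo,
        cortex_mask=cortex,
        force_field=force,
        sdr_box=box,
        construct=construct,
        seed=seed,
    )


def true_efficiency_map(scene: TensionScene, params: ForwardModelParams) -> np.ndarray:
    """Ground-truth efficiency per pixel, NaN outside the cortex.

    The tension-sensing construct converts force to efficiency; the
    controls are force-insensitive: the terminal fusion reads the
    zero-force efficiency everywhere, the rigid short linker a fixed high
    value, the long separator a fixed low value.
    """
    if scene.construct == "TSMod":
        E = force_to_fret(scene.force_field, params)
    elif scene.construct == "N-TSMod":
        E = np.full(scene.shape, params.E0)
    elif scene.construct == "5aa":
        E = np.full(scene.shape, params.high_fret_E)
    else:  # TRAF
        E = np.full(scene.shape, params.low_fret_E)
    out = np.where(scene.cortex_mask, E, np.nan)
    return out


def sensor_density_field(scene: TensionScene, params: ForwardModelParams) -> np.ndarray:
    """Static per-pixel excitation budget: zero off-cortex, mean-preserving
    log-normal expression variation on the cortex, fixed by the scene seed."""
    S = np.where(scene.cortex_mask, params.sensor_density, 0.0)
    if params.density_cv > 0:
        rng = np.random.default_rng(np.random.SeedSequence([scene.seed, 0x5EED]))
        sigma = float(np.sqrt(np.log1p(params.density_cv**2)))
        expr = rng.lognormal(-(sigma**2) / 2.0, sigma, size=scene.shape)
        S = S * expr
    return S


def _noiseless_channels(
    scene: TensionScene, params: ForwardModelParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    E = true_efficiency_map(scene, params)
    Efill = np.nan_to_num(E, nan=0.0)
    S = sensor_density_field(scene, params)
    qD_true = S * (1.0 - Efill) * params.QD * params.phi_ratio  # phiD = phi_ratio
    cF_true = S * Efill  # phiA = 1, acceptor yield folded in
    IA_sig = S  # direct acceptor excitation, FRET-independent
    bg = params.background
    ID = qD_true + bg
    IA = IA_sig + bg
    IF = cF_true + params.delta * qD_true + params.alpha * IA_sig + bg
    return ID, IA, IF


def generate_fret_stack(
    scene: TensionScene,
    params: ForwardModelParams,
    n_frames: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[ChannelStack, np.ndarray]:
    """Render a three-channel stack plus the ground-truth efficiency map.

    Each z-frame shares the same noiseless expectation; with
    ``noise="poisson"`` every channel of every frame is an independent
    Poisson draw around it.  When no generator is supplied, one is derived
    from ``scene.seed``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    ID0, IA0, IF0 = _noiseless_channels(scene, params)
    for name, chan in (("ID", ID0), ("IA", IA0), ("IF", IF0)):
        if chan.max() > _COUNT_LIMIT:
            raise OverflowError(f"channel {name} exceeds the count range")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(scene.seed))
    frames = {"ID": [], "IA": [], "IF": []}
    for _ in range(n_frames):
        if params.noise == "poisson":
            frames["ID"].append(rng.poisson(ID0).astype(np.float64))
            frames["IA"].append(rng.poisson(IA0).astype(np.float64))
            frames["IF"].append(rng.poisson(IF0).astype(np.float64))
        else:
            frames["ID"].append(ID0.copy())
            frames["IA"].append(IA0.copy())
            frames["IF"].append(IF0.copy())
    bg = float(params.background)
    stack = ChannelStack(
        ID=np.stack(frames["ID"]),
        IA=np.stack(frames["IA"]),
        IF=np.stack(frames["IF"]),
        background={"ID": bg, "IA": bg, "IF": bg},
    )
    return stack, true_efficiency_map(scene, params)


# ---------------------------------------------------------------------------
# tiling-array scenario
# ---------------------------------------------------------------------------

EFFECT_KINDS = ("intron_up", "exon_up", "exon_down", "mixed")


@dataclass
class SpliceScenario:
    """Planted splicing-misregulation scenario for two genotypes.

    Each gene is an ordered alternation exon, intron, exon, ... (always an
    odd region count, flanked by exons).  A fraction of genes is
    misregulated in the mutant; the kind of effect decides which regions
    change and in which direction.  Probe intensities are log-normal around
    a per-region baseline.

    as_fraction
        Background probability that a gene is annotated as alternatively
        spliced (the genome-wide ~25%).
    as_fraction_affected
        AS-annotation probability for genes whose misregulation touches
        splicing (intron-up, exon-up, mixed), emulating the enrichment of
        alternatively spliced genes among direct splicing-factor targets.
        ``None`` disables the enrichment.
    kind_weights
        Probabilities of the four effect kinds among affected genes.
    """

    n_genes: int = 200
    regions_per_gene: tuple[int, int] = (3, 9)
    as_fraction: float = 0.25
    as_fraction_affected: float | None = 0.6
    affected_fraction: float = 0.15
    effect_size: float = 3.0
    noise_sd: float = 0.1
    probes_per_region: int = 4
    kind_weights: tuple[float, float, float, float] = (0.15, 0.35, 0.40, 0.10)
    baseline_mean: float = 500.0
    baseline_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.regions_per_gene
        if not (1 <= lo <= hi):
            raise ValueError("regions_per_gene must be an increasing positive range")
        for name in ("as_fraction", "affected_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.as_fraction_affected is not None and not 0 <= self.as_fraction_affected <= 1:
            raise ValueError("as_fraction_affected must lie in [0, 1] or be None")
        if self.effect_size <= 1:
            raise ValueError("effect_size must exceed 1 (a multiplicative fold)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.probes_per_region < 1:
            raise ValueError("probes_per_region must be >= 1")
        if abs(sum(self.kind_weights) - 1.0) > 1e-9:
            raise ValueError("kind_weights must sum to 1")


def _odd_region_count(lo: int, hi: int, rng: np.random.Generator) -> int:
    # odd counts so every gene starts and ends with an exon
    n = int(rng.integers(lo, hi + 1))
    if n % 2 == 0:
        n = n + 1 if n < hi else n - 1
    return max(n, 1)


def generate_probe_table(
    scenario: SpliceScenario,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Draw probe intensities, gene-model annotation and ground truth.

    Returns ``(probes, annotation, truth)`` where ``probes`` has columns
    probe_id, gene, region_id, region_type, genotype ("wt" | "mut"),
    intensity; ``annotation`` has gene, as_flag; and ``truth`` carries
    "regions" (gene, region_id, region_type, fold_applied, direction) and
    "genes" (gene, effect_kind) for the planted effects only.
    """
    ss = np.random.SeedSequence(scenario.seed)
    rng_genes, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    lo, hi = scenario.regions_per_gene
    probe_rows: list[tuple] = []
    annot_rows: list[tuple] = []
    truth_regions: list[tuple] = []
    truth_genes: list[tuple] = []

    for gi in range(scenario.n_genes):
        gene = f"g{gi + 1:04d}"
        n_regions = _odd_region_count(lo, hi, rng_genes)
        types = ["exon" if k % 2 == 0 else "intron" for k in range(n_regions)]
        region_ids = [f"{gene}_r{k + 1:02d}" for k in range(n_regions)]
        baselines = rng_genes.lognormal(
            np.log(scenario.baseline_mean), scenario.baseline_log_sd, size=n_regions
        )

        affected = rng_genes.random() < scenario.affected_fraction
        kind = None
        folds = np.ones(n_regions)
        if affected:
            kind = rng_genes.choice(EFFECT_KINDS, p=scenario.kind_weights)
            exon_idx = [k for k, t in enumerate(types) if t == "exon"]
            intron_idx = [k for k, t in enumerate(types) if t == "intron"]
            if kind == "intron_up" and not intron_idx:
                kind = "exon_up"  # single-exon gene has no intron to retain
            if kind == "mixed" and not intron_idx:
                kind = "exon_up"
            chosen: list[tuple[int, float]] = []
            if kind == "intron_up":
                n_pick = int(rng_genes.integers(1, min(2, len(intron_idx)) + 1))
                picks = rng_genes.choice(intron_idx, size=n_pick, replace=False)
                chosen = [(k, scenario.effect_size) for k in picks]
            elif kind == "exon_up":
                n_pick = int(rng_genes.integers(1, min(3, len(exon_idx)) + 1))
                picks = rng_genes.choice(exon_idx, size=n_pick, replace=False)
                chosen = [(k, scenario.effect_size) for k in picks]
            elif kind == "exon_down":
                n_pick = int(rng_genes.integers(1, min(3, len(exon_idx)) + 1))
                picks = rng_genes.choice(exon_idx, size=n_pick, replace=False)
                chosen = [(k, 1.0 / scenario.effect_size) for k in picks]
            else:  # mixed: one retained intron plus one upregulated exon
                ipick = int(rng_genes.choice(intron_idx))
                epick = int(rng_genes.choice(exon_idx))
                chosen = [(ipick, scenario.effect_size), (epick, scenario.effect_size)]
            for k, fold in chosen:
                folds[k] = fold
                direction = "up" if fold > 1 else "down"
                truth_regions.append((gene, region_ids[k], types[k], fold, direction))
            truth_genes.append((gene, kind))

        splicing_touched = kind in ("intron_up", "exon_up", "mixed")
        p_as = (
            scenario.as_fraction_affected
            if (splicing_touched and scenario.as_fraction_affected is not None)
            else scenario.as_fraction
        )
        as_flag = bool(rng_genes.random() < p_as)
        annot_rows.append((gene, as_flag))

        for k in range(n_regions):
            for genotype, fold in (("wt", 1.0), ("mut", folds[k])):
                mean = baselines[k] * fold
                noise = (
                    rng_noise.lognormal(0.0, scenario.noise_sd, scenario.probes_per_region)
                    if scenario.noise_sd > 0
                    else np.ones(scenario.probes_per_region)
                )
                for p in range(scenario.probes_per_region):
                    probe_rows.append(
                        (
                            f"{region_ids[k]}_{genotype}_p{p + 1}",
                            gene,
                            region_ids[k],
                            types[k],
                            genotype,
                            mean * noise[p],
                        )
                    )

    probes = pd.DataFrame(
        probe_rows,
        columns=["probe_id", "gene", "region_id", "region_type", "genotype", "intensity"],
    )
    annotation = pd.DataFrame(annot_rows, columns=["gene", "as_flag"])
    truth = {
        "regions": pd.DataFrame(
            truth_regions,
            columns=["gene", "region_id", "region_type", "fold_applied", "direction"],
        ),
        "genes": pd.DataFrame(truth_genes, columns=["gene", "effect_kind"]),
    }
    return probes, annotation, truth


def frame_seeds(seed: int, n: int) -> Iterator[np.random.Generator]:
    """Deterministic child generators for n independent replicates."""
    for s in np.random.SeedSequence(seed).spawn(n):
        yield np.random.default_rng(s)
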
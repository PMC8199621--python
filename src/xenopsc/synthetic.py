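"""Synthetic xenograft scRNA-seq samples and preclinical cohorts with known truth.

The generator emulates the structure of a human-into-mouse pancreatic cancer
xenograft experiment: two human expression programs (epithelial cancer cells
vs myofibroblast-like pancreatic stellate cells, PSCs), a luciferase
transgene carried only by the cancer cells, mouse host cells, ambient
cross-species contamination, doublets, and a four-compartment sampling
design (primary tumour ``MsPrim``, metastasis ``MsSec``, blood ``MsBlood``,
and cultured reference cells ``Cult`` containing only the two implanted
human cell types).

Counts are drawn negative-binomially per gene with per-cell library-size
factors; ambient contamination adds a fraction ``alpha`` of each cell's
depth drawn multinomially from a pooled cross-species background; doublets
are sums of two independently drawn singlet profiles, labelled in the truth
table but presented unlabelled to the pipeline.

The cohort generator emulates the 2x2 factorial adjuvant-treatment design:
rare-cell counts are Poisson with blood-volume exposure and treatment rate
ratios, and tumour burden follows a random-intercept linear model of log10
radiant flux on treatment week with treatment x week interactions.  The
default slopes correspond to tumour doubling times of roughly 10.6 days
(control), 14.1 days (gemcitabine) and 18.5 days (HGF/c-Met inhibition).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log10

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import AnimalRecord, CountMatrix, FluxSeries, GeneAxis

_HUMAN_PREFIX = "GRCh38_"
_MOUSE_PREFIX = "GRCm38_"
_TRANSGENE_ID = "luc+"

#: singlet cell counts per compartment: (cancer, psc, mouse host)
DEFAULT_COMPOSITION: dict[str, tuple[int, int, int]] = {
    "Cult": (400, 300, 0),
    "MsPrim": (80, 40, 200),
    "MsSec": (40, 20, 150),
    "MsBlood": (62, 16, 300),
}


@dataclass
class SimConfig:
    """Parameters of the synthetic xenograft experiment.

    Attributes
    ----------
    composition
        ``{sample: (n_cancer, n_psc, n_host)}`` singlet counts per compartment.
    n_genes_per_species
        Genes in each of the human and mouse blocks (plus one transgene).
    n_marker_genes
        Planted program markers per human program: the first block of human
        genes is epithelial (KRT19/MUC1-like, up in cancer cells), the second
        myofibroblast/ECM (COL1A1/ACTA2-like, up in PSCs).
    p_luc
        Per-cell probability that a cancer cell yields detectable transgene
        UMIs.  PSC and mouse cells carry zero transgene counts before ambient
        contamination.
    alpha
        Ambient cross-species contamination fraction of each cell's depth.
    delta
        Doublet rate: ``round(delta * n_singlets)`` extra barcodes per sample
        are sums of two random singlet profiles.
    nb_theta
        Negative-binomial inverse-dispersion (larger = closer to Poisson).
    program_lfc
        log2 fold separation applied to marker blocks between the programs.
    batch_shift_sd
        SD of the per-sample log-normal gene-level batch shift (Cult = 0,
        i.e. the cultured reference defines the unshifted coordinate frame).
    mean_depth
        Mean UMIs per cell (log-normal library-size factors, sd 0.3).
    """

    composition: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION))
    n_genes_per_species: int = 800
    n_marker_genes: int = 300
    p_luc: float = 0.6
    alpha: float = 0.02
    delta: float = 0.01
    nb_theta: float = 10.0
    program_lfc: float = 2.0
    batch_shift_sd: float = 0.3
    mean_depth: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi, inc_lo, inc_hi in (
            ("p_luc", 0.0, 1.0, False, True),
            ("alpha", 0.0, 1.0, True, False),
            ("delta", 0.0, 1.0, True, False),
        ):
            v = getattr(self, name)
            ok = (v > lo or (inc_lo and v == lo)) and (v < hi or (inc_hi and v == hi))
            if not ok:
                raise ValueError(f"{name}={v} out of range")
        if self.n_marker_genes * 2 > self.n_genes_per_species:
            raise ValueError("marker blocks exceed the human gene block")
        for sample, (nc, npsc, nh) in self.composition.items():
            if min(nc, npsc, nh) < 0:
                raise ValueError(f"negative cell count for {sample}")
        if self.composition.get("Cult", (0, 0, 0))[2] != 0:
            raise ValueError("Cult must contain no mouse host cells")


def _build_gene_axis(cfg: SimConfig) -> GeneAxis:
    g = cfg.n_genes_per_species
    ids = ([f"{_HUMAN_PREFIX}HG{i:05d}" for i in range(g)]
           + [f"{_MOUSE_PREFIX}MG{i:05d}" for i in range(g)]
           + [_TRANSGENE_ID])
    tags = ["human"] * g + ["mouse"] * g + ["transgene"]
    return GeneAxis(np.array(ids, dtype=object), np.array(ids, dtype=object),
                    np.array(tags, dtype=object))


def _program_profiles(cfg: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Expected relative expression per true cell type over the full gene axis."""
    g = cfg.n_genes_per_species
    n_total = 2 * g + 1
    base_h = rng.lognormal(0.0, 1.0, size=g)
    base_m = rng.lognormal(0.0, 1.0, size=g)
    m = cfg.n_marker_genes
    fold = 2.0 ** cfg.program_lfc

    cancer = np.zeros(n_total)
    cancer[:g] = base_h
    cancer[:m] *= fold            # epithelial block up
    cancer[m:2 * m] /= fold       # myofibroblast block down

    psc = np.zeros(n_total)
    psc[:g] = base_h
    psc[:m] /= fold
    psc[m:2 * m] *= fold

    host = np.zeros(n_total)
    host[g:2 * g] = base_m

    return {k: v / v.sum() for k, v in
            {"cancer": cancer, "psc": psc, "host": host}.items()}


def _draw_counts(profile: np.ndarray, depth: float, theta: float,
                 rng: np.random.Generator) -> np.ndarray:
    mean = depth * profile
    lam = rng.gamma(theta, mean / theta)
    return rng.poisson(lam)


def generate_xenograft_samples(
    cfg: SimConfig,
) -> tuple[dict[str, CountMatrix], pd.DataFrame]:
    """Generate the four compartment count matrices plus a per-barcode truth table.

    Returns
    -------
    samples
        ``{sample_label: CountMatrix}`` for Cult, MsPrim, MsSec, MsBlood.
    truth
        One row per barcode: ``barcode``, ``sample``, ``true_species``
        (human/mouse/doublet) and ``true_type`` (cancer/psc/host/doublet).
    """
    required = {"Cult", "MsPrim", "MsSec", "MsBlood"}
    if set(cfg.composition) != required:
        raise ValueError(f"composition must cover exactly {sorted(required)}")
    if cfg.composition["Cult"][0] == 0 or cfg.composition["Cult"][1] == 0:
        raise ValueError("Cult requires both cultured cell types")

    rng = np.random.default_rng(cfg.seed)
    genes = _build_gene_axis(cfg)
    profiles = _program_profiles(cfg, rng)
    tg_idx = genes.transgene_index

    samples: dict[str, CountMatrix] = {}
    truth_rows: list[dict] = []

    for sample in ("Cult", "MsPrim", "MsSec", "MsBlood"):
        n_cancer, n_psc, n_host = cfg.composition[sample]
        types = (["cancer"] * n_cancer + ["psc"] * n_psc + ["host"] * n_host)
        n_singlet = len(types)

        # per-sample batch shift in log space; Cult is the reference frame
        if sample == "Cult" or cfg.batch_shift_sd == 0:
            shift = np.ones(len(genes))
        else:
            shift = np.exp(rng.normal(0.0, cfg.batch_shift_sd, size=len(genes)))

        shifted = {}
        for t, p in profiles.items():
            q = p * shift
            shifted[t] = q / q.sum()

        ambient_pool = np.zeros(len(genes))
        for t in set(types):
            frac = types.count(t) / n_singlet
            ambient_pool += frac * shifted[t]
        ambient_pool /= ambient_pool.sum()

        def draw_cell(cell_type: str) -> np.ndarray:
            depth = rng.lognormal(np.log(cfg.mean_depth), 0.3)
            vec = _draw_counts(shifted[cell_type], depth * (1 - cfg.alpha),
                               cfg.nb_theta, rng)
            if cell_type == "cancer" and rng.random() < cfg.p_luc:
                vec[tg_idx] += 1 + rng.poisson(2.0)
            if cfg.alpha > 0:
                n_amb = rng.binomial(max(int(round(depth)), 1), cfg.alpha)
                vec += rng.multinomial(n_amb, ambient_pool)
            return vec

        cols = [draw_cell(t) for t in types]
        barcodes = [f"{sample}_BC{i:05d}" for i in range(n_singlet)]
        for bc, t in zip(barcodes, types):
            truth_rows.append({
                "barcode": bc, "sample": sample,
                "true_species": "mouse" if t == "host" else "human",
                "true_type": t,
            })

        n_doublets = int(round(cfg.delta * n_singlet))
        for d in range(n_doublets):
            t1, t2 = rng.choice(types, size=2)
            vec = draw_cell(t1) + draw_cell(t2)
            bc = f"{sample}_DBL{d:05d}"
            cols.append(vec)
            barcodes.append(bc)
            truth_rows.append({
                "barcode": bc, "sample": sample,
                "true_species": "doublet", "true_type": "doublet",
            })

        counts = sp.csr_matrix(np.column_stack(cols))
        samples[sample] = CountMatrix(genes=genes, barcodes=barcodes,
                                      sample_label=sample, counts=counts)

    truth = pd.DataFrame(truth_rows)
    return samples, truth


# ---------------------------------------------------------------------------
# Preclinical cohort


@dataclass
class CohortConfig:
    """Parameters of the 2x2 factorial adjuvant-treatment cohort.

    Rate ratios act multiplicatively on the expected rare-cell count per
    200 uL; flux slopes are log10 fold-change of radiant flux per week.
    ``frailty_sd`` is the log-scale SD of a per-animal lognormal rate
    multiplier (mean 1) making counts overdispersed relative to Poisson,
    which mimics the heavy-tailed rare-cell counts seen in practice and is
    what the sandwich standard errors of the count models exist for.
    ``frailty_sd=0`` recovers pure Poisson counts.
    """

    n_per_arm: int = 16
    blood_volume_mean_ul: float = 340.0
    blood_volume_sd_ul: float = 40.0
    n_lpf: float = 10.0
    base_ctc_per_200ul: float = 4.0
    base_cpsc_per_200ul: float = 0.8
    rr_g_ctc: float = 0.4
    rr_hici_ctc: float = 0.5
    rr_g_cpsc: float = 1.0
    rr_hici_cpsc: float = 0.25
    rr_recurrence_ctc: float = 5.4
    frailty_sd: float = 1.6
    or_g_progression: float = 0.8
    or_hici_progression: float = 0.15
    p_progression_ctrl: float = 0.6
    n_weeks: int = 8
    slope_ctrl: float = 7 * log10(2) / 10.6
    slope_delta_g: float = 7 * log10(2) / 14.1 - 7 * log10(2) / 10.6
    slope_delta_hici: float = 7 * log10(2) / 18.5 - 7 * log10(2) / 10.6
    slope_per_baseline: float = 0.02
    baseline_mean: float = 6.0
    baseline_sd: float = 0.5
    random_intercept_sd: float = 0.3
    residual_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm <= 0:
            raise ValueError("n_per_arm must be positive")
        if self.blood_volume_mean_ul <= 0:
            raise ValueError("blood volume must be positive")


def generate_cohort(
    cfg: CohortConfig,
) -> tuple[list[AnimalRecord], list[FluxSeries], dict]:
    """Generate per-animal records and flux series for the 2x2 cohort.

    Returns the records, the longitudinal series and a ``truth`` dict with
    the generating parameters (rate ratios, odds ratios, slopes) so that
    recovery tests can compare estimates with the simulation truth.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[AnimalRecord] = []
    series: list[FluxSeries] = []
    weeks = np.arange(cfg.n_weeks + 1)
    b0 = np.log(cfg.p_progression_ctrl / (1 - cfg.p_progression_ctrl))

    i = 0
    for g in (0, 1):
        for h in (0, 1):
            for _ in range(cfg.n_per_arm):
                animal_id = f"A{i:04d}"
                set_id = f"S{i % 8}"
                volume = float(np.clip(
                    rng.normal(cfg.blood_volume_mean_ul, cfg.blood_volume_sd_ul),
                    50.0, None))
                baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd)

                logit_p = (b0 + np.log(cfg.or_g_progression) * g
                           + np.log(cfg.or_hici_progression) * h)
                p_prog = 1 / (1 + np.exp(-logit_p))
                progressive = int(rng.random() < p_prog)
                recurrence = progressive

                # per-animal lognormal frailty (mean 1): rare-cell counts are
                # overdispersed relative to Poisson, which is what the robust
                # (sandwich) standard errors in the count models account for
                u_ctc = rng.lognormal(-cfg.frailty_sd ** 2 / 2, cfg.frailty_sd)
                u_cpsc = rng.lognormal(-cfg.frailty_sd ** 2 / 2, cfg.frailty_sd)
                exposure = cfg.n_lpf * volume / 200.0
                mu_ctc = (cfg.base_ctc_per_200ul * cfg.rr_g_ctc ** g
                          * cfg.rr_hici_ctc ** h
                          * cfg.rr_recurrence_ctc ** recurrence) * exposure * u_ctc
                mu_cpsc = (cfg.base_cpsc_per_200ul * cfg.rr_g_cpsc ** g
                           * cfg.rr_hici_cpsc ** h) * exposure * u_cpsc
                raw_ctc = int(rng.poisson(mu_ctc))
                raw_cpsc = int(rng.poisson(mu_cpsc))

                slope = (cfg.slope_ctrl + cfg.slope_delta_g * g
                         + cfg.slope_delta_hici * h
                         + cfg.slope_per_baseline * (baseline - cfg.baseline_mean))
                intercept = baseline + rng.normal(0.0, cfg.random_intercept_sd)
                flux = intercept + slope * weeks + rng.normal(
                    0.0, cfg.residual_sd, size=len(weeks))
                series.append(FluxSeries(animal_id=animal_id, weeks=weeks.copy(),
                                         log10_flux=flux,
                                         baseline_log10_flux=baseline))

                records.append(AnimalRecord(
                    animal_id=animal_id, set_id=set_id, G=g, HiCi=h,
                    blood_volume_ul=volume, n_lpf=cfg.n_lpf,
                    raw_ctc=raw_ctc, raw_cpsc=raw_cpsc,
                    last_log10_flux=float(flux[-1]),
                    recurrence=recurrence, progressive=progressive,
                ))
                i += 1

    truth = {
        "rr_g_ctc": cfg.rr_g_ctc, "rr_hici_ctc": cfg.rr_hici_ctc,
        "rr_g_cpsc": cfg.rr_g_cpsc, "rr_hici_cpsc": cfg.rr_hici_cpsc,
        "or_g_progression": cfg.or_g_progression,
        "or_hici_progression": cfg.or_hici_progression,
        "slope_ctrl": cfg.slope_ctrl,
        "slope_delta_g": cfg.slope_delta_g,
        "slope_delta_hici": cfg.slope_delta_hici,
        "slope_per_baseline": cfg.slope_per_baseline,
        "random_intercept_sd": cfg.random_intercept_sd,
        "residual_sd": cfg.residual_sd,
    }
    return records, series, truth
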
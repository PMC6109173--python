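"""Synthetic-data generators with planted structure for every pipeline stage.

The generators emit exactly the formats the readers consume and record an
exhaustive ground truth, so each downstream stage can be tested for recovery
without any external download:

* a gene/TSS annotation on one synthetic chromosome,
* two-condition peak files with planted air-unique / smoke-unique / common
  classes, Poisson read counts around per-peak intensities, and a global
  log2 normalization offset between the conditions,
* target/background sequence sets with a motif planted at a configured rate,
* a two-arm, three-timepoint (day 1/2/4) expression matrix with per-subject
  random intercepts, additive batch shifts (batch confounded with subject,
  as in a two-donor one-chip design), and a planted treatment trajectory on
  smoke-unique-proximal genes that is repressed at day 1 and induced by
  day 4 (linear in day between the two deltas, hence exactly linear in the
  interaction coding of the mixed model),
* a gene-set catalog containing one set built around the planted genes.
"""
from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import MotifPWM
from .types import ExpressionStudy, GenomicInterval, Peak

log = logging.getLogger("epismoke")

CHROM = "chrSim"
BASES = np.array(list("ACGT"))
#: mono-nucleotide composition shared by target and background sequences
SEQ_COMPOSITION = np.array([0.3, 0.2, 0.2, 0.3])

#: per-class (proximal, distal, remote) placement shares
CLASS_ZONE_SHARES = {
    "common": (0.68, 0.29, 0.03),
    "smoke_unique": (0.46, 0.43, 0.11),
    "air_unique": (0.24, 0.55, 0.21),
}

_TSS_MARGIN = 2_000  # bp kept free at gene-slot edges => >= 4 kb between TSS
_PLACEMENT_GAP = 150  # bp guard band between planted peak envelopes
#: fraction of the genome holding gene slots; the rest is a TSS-free desert
#: so that "remote" (>100 kb from any TSS) placements are realizable
_GENE_TERRITORY = 0.8


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment."""

    seed: int = 0
    # annotation / peaks
    n_genes: int = 400
    genome_length: int = 20_000_000
    n_common: int = 100
    n_air_unique: int = 50
    n_smoke_unique: int = 150
    peak_width_mean: int = 600
    read_depth_mean: float = 100.0
    background_read_mean: float = 2.0
    ma_offset: float = 0.5
    # sequences
    seq_length: int = 200
    n_background_seqs: int = 500
    motif_name: str = "MOTIF_PLANTED"
    motif_rate: float = 0.5
    target_class: str = "smoke_unique"
    # expression
    n_subjects: int = 2
    n_replicates: int = 2
    sigma_subject: float = 0.3
    sigma_noise: float = 0.5
    batch_shift: float = 0.5
    planted_fraction: float = 0.8
    delta_day1: float = -1.0
    delta_day4: float = 1.0
    # gene sets
    n_gene_sets: int = 20

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "genome_length", "n_common", "n_air_unique",
            "n_smoke_unique", "peak_width_mean", "seq_length",
            "n_background_seqs", "n_subjects", "n_replicates", "n_gene_sets",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sigma_subject", "sigma_noise", "read_depth_mean",
                     "background_read_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.planted_fraction <= 1:
            raise ValueError("planted_fraction must be in [0, 1]")
        if not 0 <= self.motif_rate <= 1:
            raise ValueError("motif_rate must be in [0, 1]")
        if self.genome_length < self.n_genes * 10_000:
            raise ValueError(
                "infeasible packing: genome_length must be >= n_genes * 10 kb"
            )
        total = self.n_common + self.n_air_unique + self.n_smoke_unique
        if total > self.n_genes:
            raise ValueError(
                f"cannot plant {total} peaks with only {self.n_genes} genes"
            )


@dataclass
class GroundTruth:
    """Oracle labels for every emitted object."""

    #: input peak name -> planted class
    peak_classes: pd.DataFrame
    #: one row per planted peak: gene linkage/zone realized after placement
    peak_links: pd.DataFrame
    #: gene_id, planted flag and true fixed effects
    gene_effects: pd.DataFrame
    #: sequence id -> motif-planted flag
    sequences: pd.DataFrame
    planted_set_id: str = "GS_PLANTED"


@dataclass
class SimulatedData:
    config: SimConfig
    annotation: pd.DataFrame
    air_peaks: list[Peak]
    smoke_peaks: list[Peak]
    target_seqs: list[tuple[str, str]]
    background_seqs: list[tuple[str, str]]
    pwms: list[MotifPWM]
    study: ExpressionStudy
    catalog: dict[str, tuple[str, tuple[str, ...]]]
    truth: GroundTruth


def default_pwm_counts() -> dict[str, np.ndarray]:
    """Built-in count matrices: one plantable motif and three decoys."""

    def sharp(consensus: str) -> np.ndarray:
        counts = np.ones((4, len(consensus)))
        for j, b in enumerate(consensus):
            counts["ACGT".index(b), j] = 97
        return counts

    return {
        "MOTIF_PLANTED": sharp("TGACTCAG"),
        "DECOY_EBOX": sharp("CACGTGTC"),
        "DECOY_GC": sharp("GGGCGGAA"),
        "DECOY_AT": sharp("TTAATGCC"),
    }


def default_pwms(pseudocount: float = 0.5) -> list[MotifPWM]:
    pwms = []
    for name, counts in default_pwm_counts().items():
        probs = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
        pwms.append(MotifPWM(name, probs))
    return pwms


def simulate_annotation(
    config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Place one TSS per gene slot; returns chrom/tss/gene_id/strand.

    Genes occupy the first ~80% of the chromosome; the trailing desert has
    no TSS, so peaks placed deep inside it are genuinely remote.
    """
    spacing = int(config.genome_length * _GENE_TERRITORY) // config.n_genes
    lo = np.arange(config.n_genes) * spacing + _TSS_MARGIN
    hi = (np.arange(config.n_genes) + 1) * spacing - _TSS_MARGIN
    tss = rng.integers(lo, hi)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    return pd.DataFrame(
        {
            "chrom": CHROM,
            "tss": tss.astype(np.int64),
            "gene_id": [f"G{i + 1:05d}" for i in range(config.n_genes)],
            "strand": strands,
        }
    )


class _Occupancy:
    """Sorted non-overlapping interval set with a guard gap."""

    def __init__(self, gap: int = _PLACEMENT_GAP):
        self.starts: list[int] = []
        self.ends: list[int] = []
        self.gap = gap

    def collides(self, start: int, end: int) -> bool:
        i = bisect.bisect_left(self.starts, end + self.gap)
        if i > 0 and self.ends[i - 1] > start - self.gap:
            return True
        if i < len(self.starts) and self.starts[i] < end + self.gap:
            return True
        return False

    def add(self, start: int, end: int) -> None:
        i = bisect.bisect_left(self.starts, start)
        self.starts.insert(i, start)
        self.ends.insert(i, end)


def _draw_distance(zone: str, rng: np.random.Generator) -> int:
    if zone == "proximal":
        return int(rng.integers(-700, 701))
    if zone != "distal":
        raise ValueError(zone)
    sign = int(rng.choice([-1, 1]))
    return sign * int(rng.integers(1_500, 30_001))


def _brute_nearest(mid: int, tss: np.ndarray, genes: np.ndarray,
                   strands: np.ndarray) -> tuple[str, int]:
    d = np.abs(tss - mid)
    dmin = d.min()
    ties = np.flatnonzero(d == dmin)
    k = ties[np.argmin(genes[ties].astype(str))]
    signed = mid - int(tss[k])
    if strands[k] == "-":
        signed = -signed
    return str(genes[k]), signed


def simulate_peaks(
    config: SimConfig,
    annotation: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[list[Peak], list[Peak], pd.DataFrame, pd.DataFrame]:
    """Plant classed peaks around TSSs; returns (air, smoke, classes, links).

    ``classes`` maps every emitted input peak name to its planted class.
    ``links`` records, per planted peak, the realized nearest gene and zone
    of its merged envelope (computed by brute force over all TSS).
    """
    tss = annotation["tss"].to_numpy()
    genes = annotation["gene_id"].to_numpy()
    strands = annotation["strand"].to_numpy()

    plan = (
        [("common", i) for i in range(config.n_common)]
        + [("air_unique", i) for i in range(config.n_air_unique)]
        + [("smoke_unique", i) for i in range(config.n_smoke_unique)]
    )
    gene_order = rng.permutation(len(genes))[: len(plan)]
    occupancy = _Occupancy()
    f_air = 2.0 ** (-config.ma_offset / 2.0)
    f_smoke = 2.0 ** (config.ma_offset / 2.0)

    air_peaks: list[Peak] = []
    smoke_peaks: list[Peak] = []
    class_rows = []
    link_rows = []

    zone_names = ("proximal", "distal", "remote")
    desert_lo = int(tss.max()) + 110_000
    if desert_lo >= config.genome_length - 10_000:
        desert_lo = None  # no usable desert; remote draws fall back to distal
    for (label, idx), gi in zip(plan, gene_order):
        zone_target = rng.choice(zone_names, p=CLASS_ZONE_SHARES[label])
        if zone_target == "remote" and desert_lo is None:
            zone_target = "distal"
        anchor = int(tss[gi])
        placed = None
        for attempt in range(400):
            # a gene's ~1.4 kb proximal window can be blocked by an earlier
            # distal placement; fall back to distal after enough failures
            # (zone truth is recomputed from realized geometry afterwards)
            zone_eff = zone_target
            if attempt >= 100 and zone_target == "proximal":
                zone_eff = "distal"
            if zone_eff == "remote":
                mid = int(rng.integers(desert_lo, config.genome_length - 1_000))
            else:
                mid = anchor + _draw_distance(zone_eff, rng)
            w = int(rng.integers(config.peak_width_mean - 200,
                                 config.peak_width_mean + 201))
            start = mid - w // 2
            if start < 0 or start + w > config.genome_length:
                continue
            if label == "common":
                w2 = int(rng.integers(config.peak_width_mean - 200,
                                      config.peak_width_mean + 201))
                shift = int(rng.integers(-(w2 // 3), w // 3 + 1))
                s2 = start + shift
                env = (min(start, s2), max(start + w, s2 + w2))
                if env[0] < 0 or env[1] > config.genome_length:
                    continue
            else:
                env = (start, start + w)
            if not occupancy.collides(*env):
                placed = (start, w, env) if label != "common" else (
                    start, w, env, s2, w2
                )
                break
        if placed is None:
            raise RuntimeError(
                f"could not place {label} peak near gene {genes[gi]}; "
                "genome too crowded"
            )
        occupancy.add(placed[2][0], placed[2][1])
        lam = rng.gamma(shape=4.0, scale=config.read_depth_mean / 4.0)
        if label == "common":
            start, w, env, s2, w2 = placed
            a_name, s_name = f"air_c_{idx + 1:05d}", f"smoke_c_{idx + 1:05d}"
            air_peaks.append(Peak(
                GenomicInterval(CHROM, start, start + w), a_name,
                x_air=int(rng.poisson(lam * f_air)),
                x_smoke=int(rng.poisson(lam * f_smoke)),
            ))
            smoke_peaks.append(Peak(
                GenomicInterval(CHROM, s2, s2 + w2), s_name,
                x_air=int(rng.poisson(lam * f_air)),
                x_smoke=int(rng.poisson(lam * f_smoke)),
            ))
            class_rows += [(a_name, "common"), (s_name, "common")]
            names = f"{a_name}+{s_name}"
        else:
            start, w, env = placed
            bg = config.background_read_mean
            if label == "air_unique":
                name = f"air_u_{idx + 1:05d}"
                air_peaks.append(Peak(
                    GenomicInterval(CHROM, start, start + w), name,
                    x_air=int(rng.poisson(lam * f_air)),
                    x_smoke=int(rng.poisson(bg * f_smoke)),
                ))
            else:
                name = f"smoke_u_{idx + 1:05d}"
                smoke_peaks.append(Peak(
                    GenomicInterval(CHROM, start, start + w), name,
                    x_air=int(rng.poisson(bg * f_air)),
                    x_smoke=int(rng.poisson(lam * f_smoke)),
                ))
            class_rows.append((name, label))
            names = name
        mid_env = (env[0] + env[1]) // 2
        gene_id, signed = _brute_nearest(mid_env, tss, genes, strands)
        from .annotate import zone_classify

        link_rows.append(
            (names, label, gene_id, signed, zone_classify(signed))
        )

    classes = pd.DataFrame(class_rows, columns=["peak_name", "true_class"])
    links = pd.DataFrame(
        link_rows,
        columns=["peak_members", "true_class", "gene_id", "distance", "zone"],
    )
    log.info(
        "planted %d common, %d air-unique, %d smoke-unique peaks",
        config.n_common, config.n_air_unique, config.n_smoke_unique,
    )
    return air_peaks, smoke_peaks, classes, links


def _random_sequences(
    n: int, length: int, rng: np.random.Generator
) -> list[str]:
    draws = rng.choice(4, size=(n, length), p=SEQ_COMPOSITION)
    return ["".join(BASES[row]) for row in draws]


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_sequences(
    config: SimConfig,
    n_targets: int,
    pwm: MotifPWM,
    rng: np.random.Generator,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], pd.DataFrame]:
    """Generate composition-matched target/background FASTA records.

    Each target sequence receives, with probability ``motif_rate``, one
    embedded copy of the PWM consensus on a random strand at a random
    offset.  Background sequences are never planted.
    """
    if not 0 <= config.motif_rate <= 1:
        raise ValueError("motif_rate must be in [0, 1]")
    if config.seq_length < pwm.length:
        raise ValueError("seq_length shorter than the motif")
    targets = []
    truth_rows = []
    consensus = pwm.consensus
    raw = _random_sequences(n_targets, config.seq_length, rng)
    for i, seq in enumerate(raw):
        name = f"target_{i + 1:05d}"
        planted = bool(rng.random() < config.motif_rate)
        if planted:
            pos = int(rng.integers(0, config.seq_length - pwm.length + 1))
            instance = consensus if rng.random() < 0.5 else _revcomp(consensus)
            seq = seq[:pos] + instance + seq[pos + pwm.length:]
        targets.append((name, seq))
        truth_rows.append((name, planted))
    backgrounds = [
        (f"bg_{i + 1:05d}", seq)
        for i, seq in enumerate(
            _random_sequences(config.n_background_seqs, config.seq_length, rng)
        )
    ]
    truth_rows += [(name, False) for name, _ in backgrounds]
    truth = pd.DataFrame(truth_rows, columns=["seq_id", "planted"])
    return targets, backgrounds, truth


def planted_trajectory(config: SimConfig, day: float) -> float:
    """Smoke-minus-air effect at a given day, linear between the two deltas."""
    return config.delta_day1 + (
        (config.delta_day4 - config.delta_day1) * (day - 1.0) / 3.0
    )


def true_betas(config: SimConfig) -> tuple[float, float, float]:
    """(beta1, beta2, beta3) implied by the planted linear trajectory."""
    beta3 = (config.delta_day4 - config.delta_day1) / 3.0
    beta1 = config.delta_day1 - beta3
    return beta1, 0.0, beta3


def simulate_expression(
    config: SimConfig,
    gene_ids: list[str],
    planted_genes: set[str],
    rng: np.random.Generator,
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Two-arm, day-1/2/4 expression matrix with per-subject intercepts.

    Samples span {air, smoke} x {1, 2, 4} x subjects x technical replicates;
    batch coincides with subject and adds ``batch_shift`` per batch index.
    Planted genes get the treatment trajectory in the smoke arm only.
    """
    if config.n_subjects < 2:
        raise ValueError("expression simulation needs >= 2 subjects")
    stray = planted_genes - set(gene_ids)
    if stray:
        raise ValueError(f"planted genes not in universe: {sorted(stray)[:5]}")
    days = (1, 2, 4)
    rows = []
    for si in range(config.n_subjects):
        for arm in ("air", "smoke"):
            for day in days:
                for rep in range(1, config.n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"S{si + 1}_{arm}_d{day}_r{rep}",
                            "subject": f"S{si + 1}",
                            "treatment": arm,
                            "day": day,
                            "batch": f"B{si + 1}",
                        }
                    )
    sheet = pd.DataFrame(rows).set_index("sample_id")

    n_genes = len(gene_ids)
    n_samples = len(sheet)
    mu = rng.normal(7.0, 1.0, size=n_genes)
    subj_codes = sheet["subject"].str.slice(1).astype(int).to_numpy() - 1
    b0 = rng.normal(0.0, config.sigma_subject, size=config.n_subjects)
    batch_eff = np.arange(config.n_subjects) * config.batch_shift
    smoke = (sheet["treatment"] == "smoke").to_numpy()
    day_arr = sheet["day"].to_numpy(dtype=float)

    deltas = np.array([planted_trajectory(config, d) for d in day_arr])
    planted_mask = np.array([g in planted_genes for g in gene_ids])
    effect = np.outer(planted_mask, smoke * deltas)

    noise = rng.normal(0.0, config.sigma_noise, size=(n_genes, n_samples))
    values = (
        mu[:, None]
        + b0[subj_codes][None, :]
        + batch_eff[subj_codes][None, :]
        + effect
        + noise
    )
    matrix = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                          columns=sheet.index)
    b1, b2, b3 = true_betas(config)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "planted": planted_mask,
            "beta1": np.where(planted_mask, b1, 0.0),
            "beta2": b2,
            "beta3": np.where(planted_mask, b3, 0.0),
        }
    )
    log.info(
        "simulated expression: %d genes x %d samples, %d planted genes",
        n_genes, n_samples, int(planted_mask.sum()),
    )
    return ExpressionStudy(matrix, sheet), truth


def simulate_genesets(
    config: SimConfig,
    gene_ids: list[str],
    planted_genes: set[str],
    rng: np.random.Generator,
) -> dict[str, tuple[str, tuple[str, ...]]]:
    """A small catalog: one set around the planted genes plus random sets."""
    catalog: dict[str, tuple[str, tuple[str, ...]]] = {}
    universe = np.array(gene_ids)
    if planted_genes:
        extra = rng.choice(universe, size=min(20, len(universe)), replace=False)
        members = tuple(sorted(set(planted_genes) | set(extra)))
        catalog["GS_PLANTED"] = ("planted smoke-response genes", members)
    max_size = max(2, len(universe) // 2)
    for i in range(config.n_gene_sets - (1 if planted_genes else 0)):
        size = min(int(rng.integers(25, 201)), max_size)
        members = tuple(sorted(rng.choice(universe, size=size, replace=False)))
        catalog[f"GS_RANDOM_{i + 1:03d}"] = ("random set", members)
    return catalog


def simulate_all(config: SimConfig) -> SimulatedData:
    """Run every generator with seeds derived from config.seed."""
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    rng_ann, rng_peaks, rng_seq, rng_expr, rng_sets = (
        np.random.default_rng(s) for s in seeds
    )
    annotation = simulate_annotation(config, rng_ann)
    air, smoke, classes, links = simulate_peaks(config, annotation, rng_peaks)

    pwms = default_pwms()
    planted_pwm = next(p for p in pwms if p.name == config.motif_name)
    n_targets = {
        "common": config.n_common,
        "air_unique": config.n_air_unique,
        "smoke_unique": config.n_smoke_unique,
    }[config.target_class]
    targets, backgrounds, truth_seq = simulate_sequences(
        config, n_targets, planted_pwm, rng_seq
    )

    proximal_smoke = links[
        (links["true_class"] == "smoke_unique") & (links["zone"] == "proximal")
    ]["gene_id"].unique()
    n_plant = int(round(config.planted_fraction * len(proximal_smoke)))
    planted = set(
        rng_expr.choice(np.sort(proximal_smoke), size=n_plant, replace=False)
    ) if n_plant else set()
    gene_ids = annotation["gene_id"].tolist()
    study, truth_genes = simulate_expression(config, gene_ids, planted, rng_expr)
    catalog = simulate_genesets(config, gene_ids, planted, rng_sets)

    truth = GroundTruth(
        peak_classes=classes,
        peak_links=links,
        gene_effects=truth_genes,
        sequences=truth_seq,
    )
    return SimulatedData(
        config=config,
        annotation=annotation,
        air_peaks=air,
        smoke_peaks=smoke,
        target_seqs=targets,
        background_seqs=backgrounds,
        pwms=pwms,
        study=study,
        catalog=catalog,
        truth=truth,
    )
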
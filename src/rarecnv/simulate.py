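"""Synthetic case-control/trio CNV cohorts with known ground truth.

The generator emulates the statistical structure a rare-CNV prioritization
analysis assumes, so that every downstream stage can be exercised end-to-end
with labelled signals:

* per-sample background call counts are Poisson (default mean 32 calls per
  individual) with heavy-tailed log-normal sizes truncated at the calling
  minimum of 10 kb;
* a shared pool of polymorphic CNVs whose carriers are drawn independently in
  cases and controls at a configurable rate, so that pool members are common
  in the control cohort and removable by a frequency filter;
* spiked pathogenic CNVs (default: in 10% of cases), placed over genes,
  absent from all controls, each labelled de novo (absent from both parents)
  or inherited from a single affected parent;
* an optional case-specific excess of large calls, used to inject a
  detectable size-burden signal;
* dosage-proportional log2 expression shifts in carrier samples; and
* uniform background SNP p-value tracks with optional spiked signals.

Every function takes an explicit seed or :class:`numpy.random.Generator`;
there is no global random state, and identical configuration plus seed
reproduces byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core import CALL_COLUMNS, GAIN, LOSS, CNVCall, GeneModel, SampleRecord, Trio
from .errors import ConfigError, GenerationError

DEFAULT_FLAG_RATES = {
    "growth_gene": 0.02,
    "mgi_growth": 0.05,
    "functional_candidate": 0.05,
    "growth_tissue_expressed": 0.30,
    "decipher_overlap": 0.02,
}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Size parameters are on the natural-log scale in kb; the defaults put the
    median background call near 120 kb with a heavy upper tail, and the
    median pathogenic spike near 1 Mb (pathogenic candidates in real cohorts
    of this design span roughly 100 kb to 14 Mb).
    """

    seed: int = 0
    n_cases: int = 200
    n_controls: int = 820
    n_chromosomes: int = 4
    chromosome_length_bp: int = 50_000_000
    mean_calls_per_sample: float = 32.0
    size_log_mean: float = 4.8
    size_log_sd: float = 0.85
    calling_min_size_kb: float = 10.0
    min_markers: int = 5
    polymorphic_pool_size: int = 30
    polymorphic_carrier_rate: float = 0.05
    #: multiplicative factor applied to case background call sizes (1 = null)
    case_size_shift: float = 1.0
    #: probability that a case call above ``case_excess_min_kb`` spawns one
    #: additional same-tail call, injecting an excess of large calls in cases
    case_excess_rate: float = 0.0
    case_excess_min_kb: float = 100.0
    pathogenic_fraction: float = 0.10
    de_novo_fraction: float = 0.35
    pathogenic_size_log_mean: float = 6.9
    pathogenic_size_log_sd: float = 0.9
    dosage_log2_effect_gain: float = math.log2(1.5)
    dosage_log2_effect_loss: float = -1.0
    expression_baseline_mean: float = 8.0
    expression_baseline_sd: float = 1.0
    expression_noise_sd: float = 0.3
    snp_signal_level: float = 1e-8
    n_snps: int = 10_000
    n_genes: int = 500
    gene_flag_rates: dict = field(default_factory=lambda: dict(DEFAULT_FLAG_RATES))
    mlpa_noise_sd: float = 0.05

    def validate(self) -> None:
        counts = (
            "n_cases",
            "n_controls",
            "n_chromosomes",
            "polymorphic_pool_size",
            "n_snps",
            "n_genes",
            "min_markers",
        )
        for name in counts:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        fractions = (
            "polymorphic_carrier_rate",
            "pathogenic_fraction",
            "de_novo_fraction",
            "case_excess_rate",
        )
        for name in fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
        positive = (
            "chromosome_length_bp",
            "mean_calls_per_sample",
            "size_log_sd",
            "pathogenic_size_log_sd",
            "calling_min_size_kb",
            "case_size_shift",
        )
        for name in positive:
            v = getattr(self, name)
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v!r}")
        for name in ("expression_noise_sd", "mlpa_noise_sd", "expression_baseline_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chromosome_length_bp for c in self.chromosomes}

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration field(s): {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class GroundTruth:
    """Labels for every spiked signal in a generated cohort."""

    spiked_cnv_ids: set[str] = field(default_factory=set)
    polymorphic_cnv_ids: set[str] = field(default_factory=set)
    dosage_sensitive_gene_ids: set[str] = field(default_factory=set)
    #: call_id -> "de_novo" | "inherited_affected"
    spike_inheritance: dict[str, str] = field(default_factory=dict)
    #: call_id -> carrier (case) sample id
    spike_sample: dict[str, str] = field(default_factory=dict)
    #: pool locus tuples (chrom, start, end, cnv_type)
    polymorphic_loci: list[tuple] = field(default_factory=list)


@dataclass
class Cohort:
    """A generated cohort: call tables, pedigree, annotation and truth."""

    case_calls: pd.DataFrame
    control_calls: pd.DataFrame
    parent_calls: pd.DataFrame
    samples: dict[str, SampleRecord]
    trios: list[Trio]
    genes: list[GeneModel]
    truth: GroundTruth
    config: SimulationConfig


def _truncated_lognormal_kb(
    rng: np.random.Generator, n: int, log_mean: float, log_sd: float, min_kb: float
) -> np.ndarray:
    """Log-normal sizes (kb) truncated below at ``min_kb`` via inverse CDF."""
    if n == 0:
        return np.empty(0)
    lo = stats.norm.cdf((math.log(min_kb) - log_mean) / log_sd)
    u = rng.uniform(lo, 1.0, n)
    return np.exp(log_mean + log_sd * stats.norm.ppf(u))


def _background_frame(
    rng: np.random.Generator,
    sample_ids: list[str],
    cfg: SimulationConfig,
    size_factor: float = 1.0,
    excess_rate: float = 0.0,
) -> pd.DataFrame:
    """Vectorized background call table for a list of samples."""
    counts = rng.poisson(cfg.mean_calls_per_sample, len(sample_ids))
    total = int(counts.sum())
    samples = np.repeat(np.array(sample_ids, dtype=object), counts)
    sizes = _truncated_lognormal_kb(
        rng, total, cfg.size_log_mean, cfg.size_log_sd, cfg.calling_min_size_kb
    )
    sizes = sizes * size_factor
    if excess_rate > 0.0:
        big = sizes > cfg.case_excess_min_kb
        extra_mask = big & (rng.random(total) < excess_rate)
        n_extra = int(extra_mask.sum())
        extra_sizes = _truncated_lognormal_kb(
            rng, n_extra, cfg.size_log_mean, cfg.size_log_sd, cfg.case_excess_min_kb
        )
        sizes = np.concatenate([sizes, extra_sizes * size_factor])
        samples = np.concatenate([samples, samples[extra_mask]])
        total += n_extra
    size_bp = np.maximum(1, np.round(sizes * 1000).astype(np.int64))
    if total and size_bp.max() >= cfg.chromosome_length_bp:
        raise GenerationError(
            "drawn CNV size exceeds chromosome length; increase "
            "chromosome_length_bp or reduce size_log_mean/sd"
        )
    chrom_idx = rng.integers(0, cfg.n_chromosomes, total)
    starts = (
        rng.random(total) * (cfg.chromosome_length_bp - size_bp)
    ).astype(np.int64)
    states = np.where(rng.random(total) < 0.5, 1, 3)
    # markers roughly every 2 kb, floored at the calling minimum
    markers = np.maximum(cfg.min_markers, np.round(sizes / 2.0).astype(np.int64))
    chroms = np.array(cfg.chromosomes, dtype=object)[chrom_idx]
    df = pd.DataFrame(
        {
            "sample_id": samples,
            "chrom": chroms,
            "start": starts,
            "end": starts + size_bp,
            "copy_state": states,
            "n_markers": markers,
        }
    )
    return _finish_frame(df)


def _finish_frame(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["cnv_type"] = np.where(df["copy_state"] > 2, GAIN, LOSS)
    df["size_kb"] = (df["end"] - df["start"]) / 1000.0
    df["call_id"] = (
        df["sample_id"].astype(str)
        + ":"
        + df["chrom"].astype(str)
        + ":"
        + df["start"].astype(str)
        + "-"
        + df["end"].astype(str)
    )
    return df[CALL_COLUMNS].reset_index(drop=True)


def generate_gene_annotation(
    config: SimulationConfig, rng: np.random.Generator | int | None = None
) -> list[GeneModel]:
    """Place non-overlapping genes with exons and evidence flags.

    Genes are laid out on a per-chromosome grid (one gene per cell, jittered
    within it) so that non-overlap holds by construction; a genome too small
    to hold the requested genes raises :class:`GenerationError`.
    """
    config.validate()
    rng = _as_rng(rng, config.seed + 1)
    n = config.n_genes
    if n == 0:
        return []
    per_chrom = [n // config.n_chromosomes] * config.n_chromosomes
    for i in range(n % config.n_chromosomes):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    gid = 0
    for chrom, n_here in zip(config.chromosomes, per_chrom):
        if n_here == 0:
            continue
        cell = config.chromosome_length_bp // n_here
        if cell < 2000:
            raise GenerationError(
                f"genome too small to place {n_here} genes on {chrom} "
                f"(cell {cell} bp < 2 kb)"
            )
        max_len = min(200_000, int(cell * 0.8))
        lengths = rng.integers(10_000, max(10_001, max_len), n_here)
        lengths = np.minimum(lengths, cell - 1)
        offsets = (rng.random(n_here) * (cell - lengths)).astype(np.int64)
        starts = np.arange(n_here, dtype=np.int64) * cell + offsets
        n_exons = rng.integers(1, 9, n_here)
        flags = {
            name: rng.random(n_here) < rate
            for name, rate in config.gene_flag_rates.items()
        }
        hi = rng.uniform(0.0, 100.0, n_here)
        for i in range(n_here):
            gid += 1
            g_start = int(starts[i])
            g_len = int(lengths[i])
            k = int(n_exons[i])
            block = g_len // k
            exons = tuple(
                (g_start + j * block, g_start + j * block + max(1, block // 2))
                for j in range(k)
            )
            genes.append(
                GeneModel(
                    gene_id=f"G{gid:05d}",
                    chrom=chrom,
                    start=g_start,
                    end=g_start + g_len,
                    exons=exons,
                    hi_percentile=float(hi[i]),
                    **{name: bool(flags[name][i]) for name in flags},
                )
            )
    return genes


def _as_rng(rng, default_seed: int) -> np.random.Generator:
    if rng is None:
        return np.random.default_rng(default_seed)
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    return rng


def generate_cohort(
    config: SimulationConfig, genes: list[GeneModel] | None = None
) -> Cohort:
    """Generate case/control call tables, trios and ground truth.

    The full recipe, in order: background calls for cases, controls and
    parents; the polymorphic pool shared between cases and controls;
    pathogenic spikes over genes in a fraction of cases, each either de novo
    or copied into one parent who is then flagged affected.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if genes is None:
        genes = generate_gene_annotation(config)

    case_ids = [f"P{i + 1:04d}" for i in range(config.n_cases)]
    control_ids = [f"C{i + 1:04d}" for i in range(config.n_controls)]

    case_bg = _background_frame(
        rng, case_ids, config, config.case_size_shift, config.case_excess_rate
    )
    control_bg = _background_frame(rng, control_ids, config)
    parent_ids = [pid for cid in case_ids for pid in (f"{cid}-f", f"{cid}-m")]
    parent_bg = _background_frame(rng, parent_ids, config)

    truth = GroundTruth()

    # polymorphic pool: fixed loci, carriers drawn independently per sample
    pool_rows_case, pool_rows_control = [], []
    for k in range(config.polymorphic_pool_size):
        size_kb = float(
            _truncated_lognormal_kb(
                rng, 1, config.size_log_mean, config.size_log_sd, 50.0
            )[0]
        )
        size_bp = int(round(size_kb * 1000))
        chrom = config.chromosomes[int(rng.integers(0, config.n_chromosomes))]
        start = int(rng.integers(0, config.chromosome_length_bp - size_bp))
        state = 1 if rng.random() < 0.5 else 3
        cnv_type = LOSS if state == 1 else GAIN
        truth.polymorphic_loci.append((chrom, start, start + size_bp, cnv_type))
        markers = max(config.min_markers, int(round(size_kb / 2.0)))
        for sid in case_ids:
            if rng.random() < config.polymorphic_carrier_rate:
                pool_rows_case.append(
                    (sid, chrom, start, start + size_bp, state, markers)
                )
        for sid in control_ids:
            if rng.random() < config.polymorphic_carrier_rate:
                pool_rows_control.append(
                    (sid, chrom, start, start + size_bp, state, markers)
                )
    cols = ["sample_id", "chrom", "start", "end", "copy_state", "n_markers"]
    case_pool = _finish_frame(pd.DataFrame(pool_rows_case, columns=cols))
    control_pool = _finish_frame(pd.DataFrame(pool_rows_control, columns=cols))
    truth.polymorphic_cnv_ids = set(case_pool["call_id"])

    # pathogenic spikes
    n_spiked = int(round(config.pathogenic_fraction * config.n_cases))
    spike_rows = []
    parent_extra_rows = []
    spiked_cases = list(rng.choice(case_ids, size=n_spiked, replace=False))
    transmitting: dict[str, str] = {}  # case id -> affected parent id
    spike_meta: list[tuple[str, str, str]] = []  # (case, label, call key)
    if n_spiked and not genes:
        raise GenerationError("pathogenic spikes require a gene annotation")
    for sid in spiked_cases:
        gene = genes[int(rng.integers(0, len(genes)))]
        size_kb = float(
            _truncated_lognormal_kb(
                rng,
                1,
                config.pathogenic_size_log_mean,
                config.pathogenic_size_log_sd,
                100.0,
            )[0]
        )
        size_bp = int(round(size_kb * 1000))
        size_bp = min(size_bp, config.chromosome_length_bp - 1)
        center = (gene.start + gene.end) // 2
        start = max(0, center - size_bp // 2)
        start = min(start, config.chromosome_length_bp - size_bp)
        end = start + size_bp
        state = 1 if rng.random() < 0.5 else 3
        markers = max(config.min_markers, int(round(size_kb / 2.0)))
        spike_rows.append((sid, gene.chrom, start, end, state, markers))
        de_novo = rng.random() < config.de_novo_fraction
        label = "de_novo" if de_novo else "inherited_affected"
        if not de_novo:
            parent = f"{sid}-m" if rng.random() < 0.5 else f"{sid}-f"
            transmitting[sid] = parent
            parent_extra_rows.append((parent, gene.chrom, start, end, state, markers))
        spike_meta.append((sid, label, f"{sid}:{gene.chrom}:{start}-{end}"))
        for g in genes:
            if g.chrom == gene.chrom and g.start >= start and g.end <= end:
                truth.dosage_sensitive_gene_ids.add(g.gene_id)
    spikes = _finish_frame(pd.DataFrame(spike_rows, columns=cols))
    parent_spikes = _finish_frame(pd.DataFrame(parent_extra_rows, columns=cols))
    for sid, label, call_id in spike_meta:
        truth.spiked_cnv_ids.add(call_id)
        truth.spike_inheritance[call_id] = label
        truth.spike_sample[call_id] = sid

    def _concat(frames: list[pd.DataFrame]) -> pd.DataFrame:
        frames = [f for f in frames if not f.empty]
        if not frames:
            return case_bg.iloc[0:0]
        return pd.concat(frames, ignore_index=True)

    case_calls = _concat([case_bg, case_pool, spikes])
    control_calls = _concat([control_bg, control_pool])
    parent_calls = _concat([parent_bg, parent_spikes])

    # pedigree
    samples: dict[str, SampleRecord] = {}
    trios: list[Trio] = []
    spiked_set = set(spiked_cases)
    sexes = rng.random(config.n_cases) < 0.41
    sds = rng.normal(-2.75, 0.7, config.n_cases)
    sds = np.minimum(sds, -2.0)
    pheno = {
        "proportionate": rng.random(config.n_cases) < 0.85,
        "syndromic": rng.random(config.n_cases) < 0.345,
        "prenatal_onset": rng.random(config.n_cases) < 0.26,
        "learning_disability": rng.random(config.n_cases) < 0.26,
    }
    for i, cid in enumerate(case_ids):
        height = float(sds[i]) - (0.6 if cid in spiked_set else 0.0)
        samples[cid] = SampleRecord(
            sample_id=cid,
            group="case",
            sex="M" if sexes[i] else "F",
            height_sds=round(height, 2),
            affected=True,
            proportionate=bool(pheno["proportionate"][i]),
            syndromic=bool(pheno["syndromic"][i]),
            prenatal_onset=bool(pheno["prenatal_onset"][i]),
            learning_disability=bool(pheno["learning_disability"][i]),
        )
        father, mother = f"{cid}-f", f"{cid}-m"
        for pid, sex in ((father, "M"), (mother, "F")):
            affected = transmitting.get(cid) == pid
            samples[pid] = SampleRecord(
                sample_id=pid,
                group="parent",
                sex=sex,
                height_sds=round(float(rng.normal(-2.5, 0.4)), 2)
                if affected
                else None,
                affected=affected,
            )
        trios.append(
            Trio(
                child_id=cid,
                mother_id=mother,
                father_id=father,
                mother_affected=samples[mother].affected,
                father_affected=samples[father].affected,
            )
        )
    for cid in control_ids:
        samples[cid] = SampleRecord(sample_id=cid, group="control")

    return Cohort(
        case_calls=case_calls,
        control_calls=control_calls,
        parent_calls=parent_calls,
        samples=samples,
        trios=trios,
        genes=genes,
        truth=truth,
        config=config,
    )


def carrier_map(cohort: Cohort) -> dict[str, tuple[str, set[str]]]:
    """Map each dosage-sensitive gene to (cnv_type, carrier sample ids)."""
    gene_by_id = {g.gene_id: g for g in cohort.genes}
    spikes = cohort.case_calls[
        cohort.case_calls["call_id"].isin(cohort.truth.spiked_cnv_ids)
    ]
    out: dict[str, tuple[str, set[str]]] = {}
    for gid in cohort.truth.dosage_sensitive_gene_ids:
        g = gene_by_id[gid]
        hit = spikes[
            (spikes["chrom"] == g.chrom)
            & (spikes["start"] <= g.start)
            & (spikes["end"] >= g.end)
        ]
        if hit.empty:
            continue
        out[gid] = (hit.iloc[0]["cnv_type"], set(hit["sample_id"]))
    return out


def generate_expression(
    carriers: dict[str, tuple[str, set[str]]],
    genes: list[GeneModel],
    sample_ids: list[str],
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Log2 expression matrix with dosage shifts in carrier samples.

    ``carriers`` maps dosage-sensitive gene ids to ``(cnv_type, carrier
    sample ids)``; all other genes have zero expected group difference.
    """
    config.validate()
    rng = _as_rng(rng, config.seed + 2)
    unknown_genes = set(carriers) - {g.gene_id for g in genes}
    if unknown_genes:
        raise ConfigError(f"carriers reference unknown gene(s): {sorted(unknown_genes)}")
    for gid, (_, sids) in carriers.items():
        missing = sids - set(sample_ids)
        if missing:
            raise ConfigError(
                f"carriers of {gid} reference unknown sample(s): {sorted(missing)}"
            )
    idx = {s: j for j, s in enumerate(sample_ids)}
    baseline = rng.normal(
        config.expression_baseline_mean, config.expression_baseline_sd, len(genes)
    )
    values = baseline[:, None] + rng.normal(
        0.0, config.expression_noise_sd, (len(genes), len(sample_ids))
    )
    for i, g in enumerate(genes):
        if g.gene_id in carriers:
            cnv_type, sids = carriers[g.gene_id]
            effect = (
                config.dosage_log2_effect_gain
                if cnv_type == GAIN
                else config.dosage_log2_effect_loss
            )
            for s in sids:
                values[i, idx[s]] += effect
    return pd.DataFrame(
        values, index=pd.Index([g.gene_id for g in genes], name="gene_id"),
        columns=sample_ids,
    )


def generate_snp_track(
    config: SimulationConfig,
    signal_loci: list[tuple] | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Uniform background SNP p-values plus one spiked SNP per signal locus.

    ``signal_loci`` entries are ``(chrom, start, end)`` or
    ``(chrom, start, end, level)``; the spiked SNP sits at the locus midpoint
    with a p-value uniformly below ``level`` (default
    ``config.snp_signal_level``).
    """
    config.validate()
    rng = _as_rng(rng, config.seed + 3)
    n = config.n_snps
    chroms = np.array(config.chromosomes, dtype=object)[
        rng.integers(0, config.n_chromosomes, n)
    ]
    pos = rng.integers(0, config.chromosome_length_bp, n)
    p = rng.uniform(0.0, 1.0, n)
    p = np.nextafter(p, 1.0)  # keep p in (0, 1]
    rows = list(zip(chroms, pos.tolist(), p.tolist()))
    for locus in signal_loci or []:
        chrom, start, end = locus[0], int(locus[1]), int(locus[2])
        if chrom not in config.chrom_lengths or end > config.chromosome_length_bp:
            raise ConfigError(f"signal locus {locus} outside the genome")
        level = float(locus[3]) if len(locus) > 3 else config.snp_signal_level
        rows.append((chrom, (start + end) // 2, level * rng.uniform(0.1, 1.0)))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "p"])
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def generate_mlpa(
    calls: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """One MLPA probe per call: ratio = copy_state / 2 plus Gaussian noise."""
    config.validate()
    rng = _as_rng(rng, config.seed + 4)
    rows = []
    for i, r in enumerate(calls.itertuples(index=False)):
        ratio = r.copy_state / 2.0 + rng.normal(0.0, config.mlpa_noise_sd)
        rows.append(
            (
                f"probe{i + 1:04d}",
                f"{r.chrom}:{r.start}-{r.end}",
                r.sample_id,
                max(ratio, 1e-6),
            )
        )
    return pd.DataFrame(rows, columns=["probe_id", "locus", "sample_id", "ratio"])
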
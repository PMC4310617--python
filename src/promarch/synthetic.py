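"""Seeded synthetic-data generators with planted, recoverable structure.

Every pipeline stage can be exercised without any external download: the
generators emit transcript annotations, ChIP-seq-style peaks, TPM expression
tables and paralog families in the same shapes as the real consortium data,
with known effects planted:

* a heavy-tailed per-transcript binding-site count (zero-inflated discrete
  power law truncated at ``max_count``),
* TSS-proximal peak enrichment decaying linearly to a uniform background
  rate at ``enrichment_scale`` bases from the TSS, with an optional
  "stacked" component piled exactly at the TSS,
* a monotone (logistic in log richness) coupling between binding-site count
  and expression breadth with tunable noise,
* paralog families whose TF-repertoire Jaccard similarity and co-expression
  both decay with duplication age, and whose young duplicates are narrower
  and bind fewer TFs.

All outputs are deterministic given (config, seed): each generator derives
its RNG stream from ``config.seed`` plus a fixed per-generator offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, TranscriptAnnotation

__all__ = ["SyntheticConfig", "ParalogData", "gen_annotation", "gen_richness",
           "gen_peaks", "gen_expression", "gen_paralog_families", "sample_classes"]

_DEFAULT_TF_POOL = tuple(
    ["Pol2", "TAF1", "CTCF", "YY1", "Max", "c-Myc", "Mxi1", "Sin3A", "NFKB", "HEY1",
     "JunD", "c-Fos", "JunB", "Rad21", "SMC3", "GTF2F1", "NELFe", "SREBP2", "RXRA",
     "HSF1", "E2F1", "E2F4", "E2F6", "GATA1", "GATA2", "FOXA1", "FOXA2", "HNF4A",
     "HNF4G", "STAT1", "STAT3", "USF1", "USF2", "SP1", "NFYA", "NFYB", "ELF1",
     "ELK4", "PAX5", "ZBTB33"]
)

_AGES = ("Primate", "Mammalian", "Vertebrate", "Animal", "Eukaryotic")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic genome/expression/paralog data."""

    seed: int = 0
    # genome / annotation
    n_transcripts: int = 2000
    chrom_sizes: Mapping[str, int] = field(default_factory=lambda: {"chr1": 249_000_000})
    tss_min_spacing: int = 5000
    # binding-site richness law: zero-inflated truncated discrete power law
    zero_fraction: float = 0.25
    power_exponent: float = 1.0
    max_count: int = 60
    # peak placement
    enrichment_scale: int = 3000
    background_rate: float = 0.02  # background peaks per kb of genome
    stacking_weight: float = 0.0  # fraction of proximal peaks piled at the TSS
    peak_len_range: tuple[int, int] = (150, 350)
    tf_labels: tuple[str, ...] = _DEFAULT_TF_POOL
    pol2_label: str = "Pol2"
    # expression
    n_samples: Mapping[str, int] = field(
        default_factory=lambda: {"tissue": 179, "primary_cell": 513, "cancer_cell_line": 260}
    )
    breadth_b0: float = -2.4
    breadth_b1: float = 1.15
    breadth_noise_sd: float = 1.65
    silent_fraction: float = 0.15  # transcripts with no expression evidence anywhere
    on_tpm_logmean: float = 3.0
    on_tpm_logsd: float = 1.0
    off_tpm_max: float = 5.0
    # paralog families
    n_families: int = 300
    family_size_geom_p: float = 0.45
    max_family_size: int = 8
    age_levels: tuple[str, ...] = _AGES
    age_weights: tuple[float, ...] = (0.10, 0.15, 0.40, 0.25, 0.10)
    # per-age planted parameters, youngest -> oldest
    age_drop_rate: tuple[float, ...] = (0.08, 0.18, 0.32, 0.45, 0.60)
    age_expr_rho: tuple[float, ...] = (0.95, 0.88, 0.75, 0.60, 0.45)
    age_mean_boe: tuple[float, ...] = (0.09, 0.14, 0.24, 0.28, 0.35)
    age_mean_tfbs: tuple[float, ...] = (4.0, 5.0, 6.5, 7.5, 10.0)
    boe_noise_sd: float = 0.18
    paralog_n_samples: int = 60

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


def _rng(config: SyntheticConfig, offset: int, seed: int | None = None) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng((int(base) * 1_000_003 + offset) % (2**63 - 1))


def gen_annotation(config: SyntheticConfig, seed: int | None = None) -> list[TranscriptAnnotation]:
    """TSSs placed uniformly with a minimum spacing; strands 50/50.

    Positions are drawn as a uniform sample of slots on a ``tss_min_spacing``
    lattice per chromosome, which guarantees the spacing while staying
    (marginally) uniform.  Raises when the spacing is infeasible.
    """
    rng = _rng(config, 11, seed)
    chroms = sorted(config.chrom_sizes)
    total_slots = {c: config.chrom_sizes[c] // config.tss_min_spacing - 1 for c in chroms}
    if sum(max(0, v) for v in total_slots.values()) < config.n_transcripts:
        raise ValueError("chromosomes too short for n_transcripts at the requested TSS spacing")
    # apportion transcripts proportionally to chromosome length
    lengths = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    alloc = np.floor(config.n_transcripts * lengths / lengths.sum()).astype(int)
    while alloc.sum() < config.n_transcripts:
        alloc[int(np.argmax(lengths - alloc * config.tss_min_spacing))] += 1
    anns: list[TranscriptAnnotation] = []
    k = 0
    for c, n_c in zip(chroms, alloc):
        if n_c == 0:
            continue
        if n_c > total_slots[c]:
            raise ValueError(f"spacing infeasible on {c}")
        slots = rng.choice(total_slots[c], size=n_c, replace=False)
        slots.sort()
        for s in slots:
            tss = int((s + 1) * config.tss_min_spacing)
            strand = "+" if rng.random() < 0.5 else "-"
            anns.append(TranscriptAnnotation(f"TX{k:06d}", c, strand, tss))
            k += 1
    return anns


def gen_richness(config: SyntheticConfig, seed: int | None = None) -> np.ndarray:
    """Planted per-transcript binding-site counts.

    Zero with probability ``zero_fraction``; otherwise k in 1..max_count with
    P(k) proportional to k**(-power_exponent) (a truncated discrete power
    law, echoing the long right tail of real promoter site counts).
    """
    rng = _rng(config, 23, seed)
    k = np.arange(1, config.max_count + 1, dtype=float)
    pmf = k ** (-config.power_exponent)
    pmf /= pmf.sum()
    counts = rng.choice(np.arange(1, config.max_count + 1), size=config.n_transcripts, p=pmf)
    zeros = rng.random(config.n_transcripts) < config.zero_fraction
    counts = counts.astype(int)
    counts[zeros] = 0
    return counts


def gen_peaks(
    config: SyntheticConfig,
    annotations: Sequence[TranscriptAnnotation],
    richness: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[list[GenomicInterval], np.ndarray]:
    """Peaks = TSS-proximal component + uniform background.

    Each transcript receives its planted ``richness`` count of proximal
    peaks.  A proximal peak is centred exactly on the TSS with probability
    ``stacking_weight`` ("stacked"), otherwise at a signed offset drawn from
    a triangular density that reaches zero (pure background) at
    ``enrichment_scale`` bases.  Background peaks are uniform over each
    chromosome at ``background_rate`` per kb.  TF labels are drawn from the
    pool with Zipf-like weights (the polymerase label is the most common,
    as in real clustered ChIP-seq data); scores are uniform on 0..1000.
    """
    rng = _rng(config, 37, seed)
    if richness is None:
        richness = gen_richness(config, seed)
    if len(richness) != len(annotations):
        raise ValueError("richness must align with annotations")

    ranks = np.arange(1, len(config.tf_labels) + 1, dtype=float)
    label_w = ranks ** -0.7
    label_w /= label_w.sum()
    labels = np.asarray(config.tf_labels)
    lo_len, hi_len = config.peak_len_range

    def make_peak(chrom: str, center: int, size_limit: int) -> GenomicInterval:
        length = int(rng.integers(lo_len, hi_len + 1))
        start = max(0, min(center - length // 2, size_limit - length))
        return GenomicInterval(
            chrom,
            start,
            start + length,
            ".",
            int(rng.integers(0, 1001)),
            str(rng.choice(labels, p=label_w)),
        )

    peaks: list[GenomicInterval] = []
    scale = float(config.enrichment_scale)
    for tx, k in zip(annotations, richness):
        size = config.chrom_sizes[tx.chrom]
        for _ in range(int(k)):
            if rng.random() < config.stacking_weight:
                offset = 0.0
            else:
                # triangular density on (-scale, scale) peaked at the TSS
                offset = float(rng.triangular(-scale, 0.0, scale))
            peaks.append(make_peak(tx.chrom, int(tx.tss + offset), size))

    for chrom in sorted(config.chrom_sizes):
        size = config.chrom_sizes[chrom]
        n_bg = rng.poisson(config.background_rate * size / 1000.0)
        for center in rng.integers(0, size, size=n_bg):
            peaks.append(make_peak(chrom, int(center), size))
    return peaks, np.asarray(richness, dtype=int)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def gen_expression(
    config: SyntheticConfig,
    annotations: Sequence[TranscriptAnnotation],
    richness: np.ndarray,
    seed: int | None = None,
) -> pd.DataFrame:
    """TPM table with breadth coupled to the planted binding-site count.

    Each transcript's probability of being 'on' in a sample is
    sigmoid(b0 + b1 * log1p(richness) + eps) with per-transcript Gaussian
    noise eps; on samples receive TPM = 10 + lognormal (always above the 10
    TPM cutoff), off samples sub-threshold uniform TPM.  Columns are named
    ``<class><index>`` for the configured sample classes.
    """
    rng = _rng(config, 53, seed)
    if len(richness) != len(annotations):
        raise ValueError("richness must align with annotations")
    cols: list[str] = []
    for cls in sorted(config.n_samples):
        cols.extend(f"{cls}{i:03d}" for i in range(config.n_samples[cls]))
    n_tx, n_s = len(annotations), len(cols)

    eps = rng.normal(0.0, config.breadth_noise_sd, size=n_tx)
    p_on = _sigmoid(config.breadth_b0 + config.breadth_b1 * np.log1p(richness) + eps)
    # a fraction of transcripts never reaches the 'on' cutoff in any sample
    # (highly restricted spatial/temporal expression)
    p_on[rng.random(n_tx) < config.silent_fraction] = 0.0
    on = rng.random((n_tx, n_s)) < p_on[:, None]
    tpm = rng.uniform(0.0, config.off_tpm_max, size=(n_tx, n_s))
    n_on = int(on.sum())
    tpm[on] = 10.0 + rng.lognormal(config.on_tpm_logmean, config.on_tpm_logsd, size=n_on)
    return pd.DataFrame(tpm, index=[tx.tx_id for tx in annotations], columns=cols)


def sample_classes(config: SyntheticConfig) -> pd.Series:
    """Per-sample class labels matching :func:`gen_expression` columns."""
    pairs = []
    for cls in sorted(config.n_samples):
        pairs.extend((f"{cls}{i:03d}", cls) for i in range(config.n_samples[cls]))
    return pd.Series(dict(pairs))


@dataclass(frozen=True)
class ParalogData:
    """Synthetic gene families: pair table, per-gene repertoires and expression."""

    pairs: pd.DataFrame  # family, node, taxon, gene.x, gene.y, familySide.x, familySide.y
    genes: pd.DataFrame  # gene, family, birth_taxon, tfbs_no, boe_target
    repertoires: dict[str, frozenset]
    expression: pd.DataFrame  # gene x sample TPM


def gen_paralog_families(
    config: SyntheticConfig,
    expression: pd.DataFrame | None = None,
    seed: int | None = None,
) -> ParalogData:
    """Families with age-graded divergence of repertoire and expression.

    Each family grows by sequential duplications whose ages (taxon levels)
    are drawn from ``age_weights`` and applied oldest-first.  At a
    duplication of age a, each daughter inherits the parent's TF repertoire
    with per-label drop probability ``age_drop_rate[a]`` (plus fresh labels
    keeping the size roughly stable) and a latent expression profile
    decorrelated to ``age_expr_rho[a]``.  The newly created copy is "born" at
    that age: its target breadth and repertoire size are drawn around the
    age-specific means, so young duplicates are narrower and bind fewer TFs.
    Pairwise Jaccard similarity and co-expression therefore both decay with
    the age of the pair's duplication node.
    """
    rng = _rng(config, 71, seed)
    ages = config.age_levels
    aw = np.asarray(config.age_weights, dtype=float)
    aw /= aw.sum()
    if expression is not None:
        samples = list(expression.columns)[: config.paralog_n_samples]
    else:
        samples = [f"sample{i:03d}" for i in range(config.paralog_n_samples)]
    n_s = len(samples)
    pool = list(config.tf_labels)

    pair_rows: list[dict] = []
    gene_rows: list[dict] = []
    repertoires: dict[str, frozenset] = {}
    expr_rows: dict[str, np.ndarray] = {}
    gid = 0

    for fam_i in range(config.n_families):
        fam = f"FAM{fam_i:05d}"
        size = min(2 + rng.geometric(config.family_size_geom_p) - 1, config.max_family_size)
        node_ages = np.sort(rng.choice(len(ages), size=size - 1, p=aw))[::-1]

        # each leaf: (gene_id, ancestors [(node, side, age)], repertoire set,
        #             latent profile, birth age index)
        root_age = int(node_ages[0])
        root_size = min(max(1, rng.poisson(config.age_mean_tfbs[root_age])), len(pool))
        root_rep = set(rng.choice(pool, size=root_size, replace=False))
        leaves = [{
            "ancestors": [],
            "rep": root_rep,
            "e": rng.normal(size=n_s),
            "birth": root_age,
        }]
        for d, age in enumerate(node_ages):
            age = int(age)
            node = f"{fam}_N{d}"
            parent = leaves.pop(int(rng.integers(len(leaves))))
            drop = config.age_drop_rate[age]
            rho = config.age_expr_rho[age]
            children = []
            for side in (1, 2):
                rep = {lab for lab in parent["rep"] if rng.random() > drop}
                n_gain = rng.poisson(drop * max(1, len(parent["rep"])))
                if n_gain:
                    rep.update(rng.choice(pool, size=min(n_gain, len(pool)), replace=False))
                e = rho * parent["e"] + math.sqrt(1 - rho**2) * rng.normal(size=n_s)
                children.append({
                    "ancestors": parent["ancestors"] + [(node, side, ages[age])],
                    "rep": rep,
                    "e": e,
                    "birth": age if side == 2 else parent["birth"],
                })
            leaves.extend(children)

        # finalize genes: resize repertoire and set breadth by birth age
        fam_genes = []
        for leaf in leaves:
            gene = f"G{gid:06d}"
            gid += 1
            birth = leaf["birth"]
            target_size = max(1, rng.poisson(config.age_mean_tfbs[birth]))
            rep = list(leaf["rep"])
            rng.shuffle(rep)
            if len(rep) > target_size:
                rep = rep[:target_size]
            else:
                extra = [t for t in pool if t not in rep]
                rng.shuffle(extra)
                rep.extend(extra[: target_size - len(rep)])
            boe_target = float(np.clip(
                rng.normal(config.age_mean_boe[birth], config.boe_noise_sd), 0.02, 0.95
            ))
            n_on = int(round(boe_target * n_s))
            order = np.argsort(-leaf["e"])  # 'on' where the latent profile is highest
            tpm = rng.uniform(0.0, config.off_tpm_max, size=n_s)
            on_idx = order[:n_on]
            tpm[on_idx] = 10.0 + np.exp(
                config.on_tpm_logmean + leaf["e"][on_idx]
            )
            repertoires[gene] = frozenset(rep)
            expr_rows[gene] = tpm
            gene_rows.append({
                "gene": gene,
                "family": fam,
                "birth_taxon": ages[birth],
                "tfbs_no": len(rep),
                "boe_target": boe_target,
            })
            fam_genes.append({**leaf, "gene": gene})

        # pair table: every leaf pair through its most recent common node
        for i in range(len(fam_genes)):
            for j in range(i + 1, len(fam_genes)):
                a, b = fam_genes[i], fam_genes[j]
                mrca = None
                for (na, sa, ta), (nb, sb, tb) in zip(a["ancestors"], b["ancestors"]):
                    if na != nb:
                        break
                    mrca = (na, sa, sb, ta)
                    if sa != sb:
                        break
                if mrca is None:
                    continue
                node, sa, sb, taxon = mrca
                pair_rows.append({
                    "family": fam, "node": node, "taxon": taxon,
                    "gene.x": a["gene"], "gene.y": b["gene"],
                    "familySide.x": sa, "familySide.y": sb,
                })

    pairs = pd.DataFrame(pair_rows)
    genes = pd.DataFrame(gene_rows).set_index("gene")
    expr = pd.DataFrame.from_dict(expr_rows, orient="index", columns=samples)
    return ParalogData(pairs, genes, repertoires, expr)
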
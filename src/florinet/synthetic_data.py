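"""Synthetic dataset generator with full ground truth.

Emulates the study design the pipeline targets: a small uniform-composition
genome with annotated genes, one binding motif per TF with consensus sites
planted in the promoters of true regulatory targets, a negative-binomial
count matrix over three conditions (C control, I induced-but-not-flowered,
F flowered) with planted TF-target coexpression and >= 2-fold condition
effects, curated gene lists containing a planted "differentially wired" TF
family, and error-free shotgun reads for the k-mer survey.

Regulatory structure. Each TF carries a latent per-sample activity (condition
mean + Gaussian jitter); a true target's log2 mean tracks its TF's activity
with the configured sign and coupling weight, so planted pairs are strongly
rank-correlated while unrelated pairs are not. TFs of the planted
differential family share one latent factor that is active in the flowered
program only: their targets track the factor in C and F samples but are
decoupled (independent jitter) in I samples, so family edges appear in the
C-F network and vanish from the C-I network — the positive control for the
differential-network stage.

All randomness flows from one master seed through four independent child
streams (genome, sites, expression, reads), so every artifact is reproducible
byte-for-byte and the read simulator cannot perturb the expression draw.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CountMatrix,
    GeneRecord,
    MotifModel,
    SequenceRecord,
    write_count_matrix,
    write_fasta,
    write_fastq,
    write_gene_sets,
    write_gff3_genes,
    write_meme_motifs,
    write_tf_map,
)
from .promoters import PromoterWindowConfig, promoter_interval
from .seqcodes import ALPHABET, revcomp

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate_genome_annotation",
    "generate_motif_set_and_sites",
    "simulate_expression_matrix",
    "simulate_reads",
    "generate_dataset",
    "simulate_de_benchmark",
]

CONDITIONS = ("C", "I", "F")


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 200_000
    n_genes: int = 300
    n_tfs: int = 20
    gene_length: int = 300
    motif_width: int = 10
    motif_information_content: float = 1.8  # bits per column
    n_true_edges: int = 150
    frac_negative_edges: float = 0.25
    family_name: str = "AP2-ERF"
    family_size: int = 6
    family_pool_size: int = 12
    replicates_per_condition: int = 4
    planted_fold_change: float = 4.0
    nb_dispersion: float = 0.02
    mean_expression: float = 1000.0
    activity_sd: float = 0.7  # log2 units of latent TF activity jitter
    coupling_weight: float = 2.5  # target log2 response per unit TF activity
    tf_idio_sd: float = 0.2  # family-TF idiosyncratic jitter around the factor
    bystander_sd: float = 0.3
    baseline_log2_sd: float = 0.8
    frac_bystander_de: float = 0.2
    read_length: int = 150
    coverage: float = 30.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.replicates_per_condition < 2:
            raise ValueError("need >= 2 replicates per condition")
        if self.planted_fold_change < 1:
            raise ValueError("planted_fold_change must be >= 1")
        if not (0 <= self.frac_negative_edges <= 1):
            raise ValueError("frac_negative_edges must lie in [0, 1]")
        if self.n_tfs < self.family_size:
            raise ValueError("family_size exceeds n_tfs")
        if self.n_genes <= self.n_tfs:
            raise ValueError("need non-TF genes to serve as targets")
        if self.motif_width > 600:
            raise ValueError("motif wider than the promoter window")
        # capacity: genes with promoter clearance must fit in the genome
        if self._slots_per_chrom() * self.n_chrom < self.n_genes:
            raise ValueError(
                f"cannot place {self.n_genes} genes with promoter clearance in "
                f"{self.n_chrom} x {self.chrom_len} bp"
            )

    def _slots_per_chrom(self) -> int:
        stride = self.gene_length + 700
        return max((self.chrom_len - 1400) // stride, 0)

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i + 1:03d}" for i in range(self.n_tfs)]

    @property
    def gene_ids(self) -> list[str]:
        other = [f"G{i + 1:04d}" for i in range(self.n_genes - self.n_tfs)]
        return self.tf_ids + other

    @property
    def family_tfs(self) -> list[str]:
        return self.tf_ids[self.n_tfs - self.family_size :]

    @property
    def sample_ids(self) -> list[str]:
        return [f"{c}{r + 1}" for c in CONDITIONS for r in range(self.replicates_per_condition)]


@dataclass
class GroundTruth:
    """Everything needed to score every downstream stage."""

    true_edges: set[tuple[str, str, str]]  # (tf, target, sign)
    planted_sites: list[tuple[str, int, str, str]]  # (gene, promoter offset, strand, motif)
    de_genes: dict[str, dict[str, float]] = field(default_factory=dict)  # comparison -> gene -> lfc
    differential_family: set[str] = field(default_factory=set)
    family_name: str = ""

    def to_json(self, path: str | Path) -> None:
        obj = {
            "true_edges": sorted(list(e) for e in self.true_edges),
            "planted_sites": [list(s) for s in self.planted_sites],
            "de_genes": {k: dict(sorted(v.items())) for k, v in sorted(self.de_genes.items())},
            "differential_family": sorted(self.differential_family),
            "family_name": self.family_name,
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        return cls(
            true_edges={tuple(e) for e in obj["true_edges"]},
            planted_sites=[tuple(s) for s in obj["planted_sites"]],
            de_genes={k: dict(v) for k, v in obj["de_genes"].items()},
            differential_family=set(obj["differential_family"]),
            family_name=obj["family_name"],
        )


def _streams(config: SyntheticConfig) -> dict[str, np.random.Generator]:
    names = ("genome", "sites", "expression", "reads", "genesets")
    children = np.random.SeedSequence(config.seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# genome + annotation


def generate_genome_annotation(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[list[SequenceRecord], list[GeneRecord]]:
    """Uniform-background genome with non-overlapping, promoter-clear genes.

    Every gene keeps >= 700 bp of intergenic space on both sides (and 700 bp
    chromosome margins), so the 600-bp promoter window is never clipped and
    never overlaps a neighbouring gene's window.
    """
    rng = rng if rng is not None else _streams(config)["genome"]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = [
        SequenceRecord(
            f"chr{ci + 1}",
            bases[rng.integers(0, 4, size=config.chrom_len)].tobytes().decode("ascii"),
        )
        for ci in range(config.n_chrom)
    ]
    per = [config.n_genes // config.n_chrom] * config.n_chrom
    for i in range(config.n_genes % config.n_chrom):
        per[i] += 1
    stride_min = config.gene_length + 700
    genes: list[GeneRecord] = []
    gene_ids = config.gene_ids
    gi = 0
    for ci, count in enumerate(per):
        if count == 0:
            continue
        usable = config.chrom_len - 1400
        stride = usable // count
        if stride < stride_min:
            raise ValueError("genes cannot be placed without promoter overlap")
        for j in range(count):
            slack = stride - stride_min
            start = 700 + j * stride + int(rng.integers(0, slack + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneRecord(gene_ids[gi], f"chr{ci + 1}", start, start + config.gene_length, strand)
            )
            gi += 1
    return genome, genes


# ---------------------------------------------------------------------------
# motifs + planted sites + regulatory structure


def _solve_pmax(ic_target: float) -> float:
    """Consensus-column probability whose information content matches the target."""

    def ic(p: float) -> float:
        q = (1.0 - p) / 3.0
        h = -p * math.log2(p) - (3 * q * math.log2(q) if q > 0 else 0.0)
        return 2.0 - h

    lo, hi = 0.2501, 1.0 - 1e-12
    if ic_target >= 2.0:
        return 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if ic(mid) < ic_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _plan_edges(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[set[tuple[str, str, str]], dict[str, str]]:
    """Choose true edges and per-target signs.

    Family TFs draw targets from one shared pool (the co-regulated floral
    program); other TFs get disjoint private target sets. Signs are assigned
    per target so that a pool gene tracks the family factor consistently.
    """
    tf_ids = config.tf_ids
    family = set(config.family_tfs)
    non_tf = [g for g in config.gene_ids if g not in set(tf_ids)]
    pool = non_tf[: config.family_pool_size]
    private = non_tf[config.family_pool_size :]

    quota = {tf: config.n_true_edges // config.n_tfs for tf in tf_ids}
    for tf in tf_ids[: config.n_true_edges % config.n_tfs]:
        quota[tf] += 1
    if max(quota[t] for t in family) > len(pool):
        raise ValueError("family_pool_size too small for the per-TF edge quota")
    need_private = sum(quota[t] for t in tf_ids if t not in family)
    if need_private > len(private):
        raise ValueError("not enough non-TF genes for private target sets")

    target_sign: dict[str, str] = {}
    for g in pool:
        target_sign[g] = "-" if rng.random() < config.frac_negative_edges else "+"

    edges: set[tuple[str, str, str]] = set()
    private_iter = iter(rng.permutation(private))
    for tf in tf_ids:
        if tf in family:
            targets = rng.choice(len(pool), size=quota[tf], replace=False)
            for idx in targets:
                g = pool[int(idx)]
                edges.add((tf, g, target_sign[g]))
        else:
            for _ in range(quota[tf]):
                g = str(next(private_iter))
                sign = "-" if rng.random() < config.frac_negative_edges else "+"
                target_sign[g] = sign
                edges.add((tf, g, sign))
    return edges, target_sign


def generate_motif_set_and_sites(
    config: SyntheticConfig,
    genome: Sequence[SequenceRecord],
    genes: Sequence[GeneRecord],
    rng: np.random.Generator | None = None,
) -> tuple[list[MotifModel], dict[str, str], list[SequenceRecord], GroundTruth]:
    """One motif per TF; consensus sites planted in true targets' promoters.

    Returns (motifs, tf->motif map, genome with sites written in,
    ground truth carrying the true edges and planted site coordinates).
    """
    rng = rng if rng is not None else _streams(config)["sites"]
    edges, _ = _plan_edges(config, rng)

    pmax = _solve_pmax(config.motif_information_content)
    off_p = (1.0 - pmax) / 3.0
    motifs: list[MotifModel] = []
    tf_map: dict[str, str] = {}
    consensus_of: dict[str, str] = {}
    for tf in config.tf_ids:
        cons_codes = rng.integers(0, 4, size=config.motif_width)
        mat = np.full((config.motif_width, 4), off_p)
        mat[np.arange(config.motif_width), cons_codes] = pmax
        motif_id = f"M_{tf}"
        motifs.append(MotifModel(motif_id, mat, n_sites=20))
        tf_map[tf] = motif_id
        consensus_of[tf] = "".join(ALPHABET[int(b)] for b in cons_codes)

    window = PromoterWindowConfig()
    if window.width < config.motif_width:
        raise ValueError("promoter too short for the motif")
    gene_by_id = {g.gene_id: g for g in genes}
    chrom_seq = {rec.id: bytearray(rec.sequence, "ascii") for rec in genome}
    occupied: dict[str, list[tuple[int, int]]] = {}
    sites: list[tuple[str, int, str, str]] = []
    w = config.motif_width
    for tf, target, _sign in sorted(edges):
        gene = gene_by_id[target]
        lo, hi, clipped = promoter_interval(gene, window, config.chrom_len)
        plen = hi - lo
        if plen < w:
            raise ValueError(f"promoter of {target} too short for motif width {w}")
        used = occupied.setdefault(target, [])
        for _attempt in range(200):
            off = int(rng.integers(0, plen - w + 1))
            if all(off + w <= a or off >= b for a, b in used):
                break
        else:
            raise ValueError(f"could not place a free site in promoter of {target}")
        used.append((off, off + w))
        site_strand = "+" if rng.random() < 0.5 else "-"
        cons = consensus_of[tf]
        # transcription-orientation offset -> forward-genome coordinates
        if gene.strand == "+":
            gpos = lo + off
            written = cons if site_strand == "+" else revcomp(cons)
        else:
            gpos = hi - off - w
            written = revcomp(cons) if site_strand == "+" else cons
        chrom_seq[gene.chrom][gpos : gpos + w] = written.encode("ascii")
        sites.append((target, off, site_strand, tf_map[tf]))

    planted = [SequenceRecord(rec.id, chrom_seq[rec.id].decode("ascii")) for rec in genome]
    truth = GroundTruth(
        true_edges=edges,
        planted_sites=sorted(sites),
        differential_family=set(config.family_tfs),
        family_name=config.family_name,
    )
    return motifs, tf_map, planted, truth


# ---------------------------------------------------------------------------
# expression


def simulate_expression_matrix(
    config: SyntheticConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> CountMatrix:
    """NB counts with planted coexpression and condition effects.

    Fills ``truth.de_genes`` with the planted log2 fold changes (deterministic
    condition-mean differences of magnitude >= log2(planted_fold_change)) for
    the I-vs-C, F-vs-C and F-vs-I comparisons.
    """
    rng = rng if rng is not None else _streams(config)["expression"]
    genes = config.gene_ids
    samples = config.sample_ids
    reps = config.replicates_per_condition
    cond_of = np.repeat(np.arange(3), reps)  # 0=C 1=I 2=F
    n_s = len(samples)
    lfc = math.log2(config.planted_fold_change)
    family = set(config.family_tfs)

    parents: dict[str, tuple[str, str]] = {}
    for tf, target, sign in sorted(truth.true_edges):
        parents[target] = (tf, sign)  # single parent for private targets;
        # pool targets share the family factor, any family parent is equivalent
    family_targets = {t for tf, t, s in truth.true_edges if tf in family}

    # condition-mean activity per TF (log2 units)
    tf_mu = {}
    for tf in config.tf_ids:
        if tf in family:
            tf_mu[tf] = np.array([0.0, 0.0, lfc])
        else:
            tf_mu[tf] = np.array(
                [0.0, rng.choice([-lfc, lfc]), rng.choice([-lfc, lfc])]
            )
    fam_mu = np.array([0.0, 0.0, lfc])
    fam_factor = fam_mu[cond_of] + rng.normal(0, config.activity_sd, n_s)

    z: dict[str, np.ndarray] = {}
    for tf in config.tf_ids:
        if tf in family:
            z[tf] = fam_factor + rng.normal(0, config.tf_idio_sd, n_s)
        else:
            z[tf] = tf_mu[tf][cond_of] + rng.normal(0, config.activity_sd, n_s)

    base = math.log2(config.mean_expression) + rng.normal(
        0, config.baseline_log2_sd, len(genes)
    )
    L = np.empty((len(genes), n_s))
    det_mu = np.zeros((len(genes), 3))  # deterministic condition log2 means
    w = config.coupling_weight
    in_I = cond_of == 1

    bystander_rows: list[int] = []
    for gi, g in enumerate(genes):
        if g in z:  # a TF
            L[gi] = base[gi] + z[g]
            det_mu[gi] = tf_mu[g]
        elif g in family_targets:
            s = 1.0 if parents[g][1] == "+" else -1.0
            row = base[gi] + s * w * fam_factor
            row[in_I] = base[gi] + rng.normal(0, config.activity_sd, in_I.sum())
            L[gi] = row
            det_mu[gi] = s * w * fam_mu
            det_mu[gi, 1] = 0.0  # decoupled in I
        elif g in parents:
            tf, sgn = parents[g]
            s = 1.0 if sgn == "+" else -1.0
            L[gi] = base[gi] + s * w * z[tf]
            det_mu[gi] = s * w * tf_mu[tf]
        else:
            bystander_rows.append(gi)
            L[gi] = base[gi] + rng.normal(0, config.bystander_sd, n_s)

    # a fraction of bystanders carry their own condition effects
    n_by_de = int(round(config.frac_bystander_de * len(bystander_rows)))
    for gi in rng.choice(bystander_rows, size=n_by_de, replace=False) if n_by_de else []:
        mu = np.array([0.0, rng.choice([-lfc, 0.0, lfc]), rng.choice([-lfc, lfc])])
        L[gi] += mu[cond_of]
        det_mu[gi] += mu

    mu_counts = np.exp2(L)
    if config.nb_dispersion > 0:
        nb_n = 1.0 / config.nb_dispersion
        counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mu_counts))
    else:
        counts = rng.poisson(mu_counts)

    # planted DE truth from deterministic condition means
    comps = {"I-vs-C": (0, 1), "F-vs-C": (0, 2), "F-vs-I": (1, 2)}
    thresh = 0.999 * lfc if lfc > 0 else np.inf
    truth.de_genes = {
        name: {
            genes[gi]: float(det_mu[gi, b] - det_mu[gi, a])
            for gi in range(len(genes))
            if abs(det_mu[gi, b] - det_mu[gi, a]) >= thresh
        }
        for name, (a, b) in comps.items()
    }

    df = pd.DataFrame(counts.astype(np.int64), index=genes, columns=samples)
    cond = pd.Series([s[0] for s in samples], index=samples, name="condition")
    return CountMatrix(df, cond)


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    config: SyntheticConfig,
    genome: Sequence[SequenceRecord],
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Uniform shotgun reads from both strands at the configured coverage."""
    rng = rng if rng is not None else _streams(config)["reads"]
    rl = config.read_length
    lens = np.array([len(rec.sequence) for rec in genome])
    if (lens < rl).any():
        raise ValueError("read_length exceeds a chromosome length")
    total = int(lens.sum())
    n_reads = int(math.ceil(config.coverage * total / rl))
    starts_per = lens - rl + 1
    probs = starts_per / starts_per.sum()
    chrom_idx = rng.choice(len(genome), size=n_reads, p=probs)
    decode_tab = np.frombuffer(b"ACGT", dtype=np.uint8)
    comp = np.array([3, 2, 1, 0], dtype=np.uint8)
    out: list[tuple[str, str]] = []
    rid = 0
    from .seqcodes import encode

    for ci, rec in enumerate(genome):
        n_c = int((chrom_idx == ci).sum())
        if n_c == 0:
            continue
        codes = encode(rec.sequence)
        pos = rng.integers(0, starts_per[ci], size=n_c)
        mat = codes[pos[:, None] + np.arange(rl)[None, :]]
        rev = rng.random(n_c) < 0.5
        mat[rev] = comp[mat[rev, ::-1]]
        if config.error_rate > 0:
            err = rng.random(mat.shape) < config.error_rate
            shift = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
            mat = np.where(err, (mat + shift) % 4, mat).astype(np.uint8)
        chars = decode_tab[mat]
        for r in range(n_c):
            strand = "-" if rev[r] else "+"
            out.append((f"read{rid}:{rec.id}:{int(pos[r])}:{strand}", chars[r].tobytes().decode("ascii")))
            rid += 1
    return out


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: list[SequenceRecord]
    genes: list[GeneRecord]
    motifs: list[MotifModel]
    tf_map: dict[str, str]
    counts: CountMatrix
    gene_sets: dict[str, set[str]]
    truth: GroundTruth

    def write(self, out_dir: str | Path, include_reads: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, out / "genome.fasta")
        write_gff3_genes(self.genes, out / "genes.gff3")
        write_meme_motifs(self.motifs, out / "motifs.meme")
        write_tf_map(self.tf_map, out / "tf_map.tsv")
        write_count_matrix(self.counts, out / "counts.tsv", out / "conditions.tsv")
        write_gene_sets(self.gene_sets, out / "genesets.tsv")
        self.truth.to_json(out / "truth.json")
        if include_reads:
            write_fastq(simulate_reads(self.config, self.genome), out / "reads.fastq")


def generate_dataset(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Full dataset: genome, annotation, motifs+sites, counts, gene lists, truth."""
    streams = _streams(config)
    genome, genes = generate_genome_annotation(config, streams["genome"])
    motifs, tf_map, planted_genome, truth = generate_motif_set_and_sites(
        config, genome, genes, streams["sites"]
    )
    counts = simulate_expression_matrix(config, truth, streams["expression"])

    gs_rng = streams["genesets"]
    targets = {t for _tf, t, _s in truth.true_edges}
    bystanders = [g for g in config.gene_ids if g not in targets and g not in set(config.tf_ids)]
    decoys = {str(g) for g in gs_rng.choice(bystanders, size=min(10, len(bystanders)), replace=False)}
    stable_tfs = [t for t in config.tf_ids if t not in truth.differential_family]
    gene_sets = {
        "floral": targets | decoys,
        config.family_name: set(config.family_tfs),
        "TCP": set(stable_tfs[: min(4, len(stable_tfs))]),
        "TF": set(config.tf_ids),
    }
    return SyntheticDataset(
        config=config,
        genome=planted_genome,
        genes=genes,
        motifs=motifs,
        tf_map=tf_map,
        counts=counts,
        gene_sets=gene_sets,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# standalone DE benchmark


def simulate_de_benchmark(
    n_genes: int = 2000,
    replicates: int = 4,
    dispersion: float = 0.1,
    n_de: int = 0,
    fold: float = 4.0,
    mean_expression: float = 200.0,
    seed: int = 0,
) -> tuple[CountMatrix, set[str]]:
    """Two-group NB matrix (conditions C vs F) with optional planted DE genes.

    The first ``n_de`` genes get a ``fold``-change in F (alternating up/down);
    the rest are null. Used to calibrate the DE test's type-I error and power.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples = [f"C{r + 1}" for r in range(replicates)] + [f"F{r + 1}" for r in range(replicates)]
    base = mean_expression * np.exp(rng.normal(0, 0.5, n_genes))
    mu = np.tile(base[:, None], (1, 2 * replicates))
    de_genes = set(genes[:n_de])
    for i in range(n_de):
        factor = fold if i % 2 == 0 else 1.0 / fold
        mu[i, replicates:] *= factor
    if dispersion > 0:
        nb_n = 1.0 / dispersion
        counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))
    else:
        counts = rng.poisson(mu)
    df = pd.DataFrame(counts.astype(np.int64), index=genes, columns=samples)
    cond = pd.Series([s[0] for s in samples], index=samples, name="condition")
    return CountMatrix(df, cond), de_genes
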
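"""Synthetic study generator.

Emulates the statistical structure of a cell-cycle translatome study so
that every downstream stage is testable without external data: a latent
multivariate-normal gene abundance shared by four assays (mRNA-Seq,
ribosome profiling RP, nascent-chain proteomics PP, steady-state protein
PSS), negative-binomial sequencing counts with 4 replicates per phase,
log-normal MS intensities with abundance-dependent (logistic) missingness
and 3 replicates per phase plus a non-specific control triplicate,
planted M/G1 differential expression, a toy transcriptome exercising the
UTR/ORF repair edge cases, footprint reads with adapter and decoy
contaminants, and a scale-free PPI network with planted connected
modules.

Every generator is a pure function of its configuration and seed.

Default marginal Spearman targets among (mRNA, RP, PP, PSS) follow the
observed study-scale structure: rho(PSS,RP)=0.70, rho(PSS,PP)=0.68,
rho(PSS,mRNA)=0.61, rho(RP,PP)=0.63.  The two mRNA cross-terms
(rho(mRNA,RP)=0.74, rho(mRNA,PP)=0.58) are set so the implied
conditional structure also reproduces the observed partial correlations
(~0.45-0.52 for PSS with RP/PP given mRNA, ~0.37 for RP with PP given
mRNA) and a small positive contribution of mRNA to steady-state protein
prediction on top of RP and PP (partial ~0.11).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .reads import DEFAULT_ADAPTER, Read
from .reference import TranscriptRecord

ASSAYS = ("mRNA", "RP", "PP", "PSS")
PHASES = ("G1", "M")

#: Marginal Spearman correlation targets, order (mRNA, RP, PP, PSS).
DEFAULT_TARGET_CORR = np.array(
    [
        [1.00, 0.74, 0.58, 0.61],
        [0.74, 1.00, 0.63, 0.70],
        [0.58, 0.63, 1.00, 0.68],
        [0.61, 0.70, 0.68, 1.00],
    ]
)


def _spearman_to_pearson(r: np.ndarray) -> np.ndarray:
    """Latent normal correlation realizing a target Spearman correlation."""
    rho = 2 * np.sin(np.pi * np.asarray(r, dtype=float) / 6)
    np.fill_diagonal(rho, 1.0)
    return rho


@dataclass
class StudyConfig:
    """Parameters of the synthetic study world.

    Counts use variance = mu + mu^2 / ``nb_dispersion``; MS intensities
    are on the log2 scale with detection probability logistic in
    intensity around ``missingness_midpoint``.  ``log2fc_scale`` is the
    magnitude of every planted M/G1 log2 fold-change (random sign);
    ``de_sign_agreement`` is the probability that a DE gene's PP shift
    shares the sign of its RP shift.
    """

    n_genes: int = 2000
    n_rp_reps: int = 4
    n_pp_reps: int = 3
    de_fraction: float = 0.10
    log2fc_scale: float = 3.0
    nb_dispersion: float = 10.0
    missingness_midpoint: float = 20.5
    missingness_scale: float = 1.0
    target_corr: np.ndarray = field(default_factory=lambda: DEFAULT_TARGET_CORR.copy())
    rng_seed: int = 0
    # secondary knobs of the stated world
    base_log2_count: float = 6.0
    latent_sd: float = 2.0
    intensity_base: float = 24.0
    intensity_latent_scale: float = 1.5
    intensity_noise_sd: float = 0.5
    depth_jitter_sd: float = 0.15
    de_sign_agreement: float = 1.0

    def __post_init__(self):
        self.target_corr = np.asarray(self.target_corr, dtype=float)
        if not (0 < self.de_fraction < 1):
            raise ValueError("de_fraction must lie in (0, 1)")
        if self.log2fc_scale <= 0 or self.nb_dispersion <= 0:
            raise ValueError("log2fc_scale and nb_dispersion must be positive")
        c = self.target_corr
        if c.shape != (4, 4) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1):
            raise ValueError("target_corr must be symmetric 4x4 with unit diagonal")
        evals = np.linalg.eigvalsh(_spearman_to_pearson(c))
        if evals.min() < -1e-8:
            raise ValueError(
                f"target_corr is not positive semidefinite (min latent eigenvalue {evals.min():.3g})"
            )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "target_corr" in raw:
            raw["target_corr"] = np.asarray(raw["target_corr"], dtype=float)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items()}
        data["target_corr"] = self.target_corr.tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators."""

    de_genes: set = field(default_factory=set)
    lfc_rp: pd.Series | None = None  # per-gene true log2 M/G1 fold-change (RP)
    lfc_pp: pd.Series | None = None
    planted_modules: list = field(default_factory=list)

    def to_json(self, path) -> None:
        data = {
            "de_genes": sorted(self.de_genes),
            "lfc_rp": {} if self.lfc_rp is None else self.lfc_rp.to_dict(),
            "lfc_pp": {} if self.lfc_pp is None else self.lfc_pp.to_dict(),
            "planted_modules": [sorted(m) for m in self.planted_modules],
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)


@dataclass
class ExpressionStudy:
    """Generated expression tables keyed by (assay, phase).

    mRNA/RP tables hold NB counts (genes x replicates); PP/PSS tables
    hold raw log2 intensities with NaN for undetected values.
    ``pp_control`` is the 3-replicate non-specific control arm and
    ``coverage`` a per-gene footprint-coverage fraction tied to RP
    abundance.
    """

    tables: dict
    pp_control: pd.DataFrame
    coverage: pd.Series
    latent: pd.DataFrame
    truth: SyntheticTruth


def generate_expression_study(config: StudyConfig) -> ExpressionStudy:
    """Draw the full four-assay, two-phase expression study."""
    rng = np.random.default_rng(config.rng_seed)
    genes = pd.Index([f"G{i:05d}" for i in range(config.n_genes)], name="gene")

    latent_corr = _spearman_to_pearson(config.target_corr)
    z = rng.multivariate_normal(np.zeros(4), latent_corr, size=config.n_genes, method="cholesky")
    latent = pd.DataFrame(z, index=genes, columns=list(ASSAYS))

    n_de = int(np.floor(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    de_genes = set(genes[de_idx])
    sign_rp = rng.choice([-1.0, 1.0], size=n_de)
    agree = rng.random(n_de) < config.de_sign_agreement
    sign_pp = np.where(agree, sign_rp, -sign_rp)

    lfc_rp = pd.Series(0.0, index=genes)
    lfc_pp = pd.Series(0.0, index=genes)
    lfc_rp.iloc[de_idx] = sign_rp * config.log2fc_scale
    lfc_pp.iloc[de_idx] = sign_pp * config.log2fc_scale

    tables: dict = {}
    for assay in ("mRNA", "RP"):
        base = config.base_log2_count + config.latent_sd * latent[assay].to_numpy()
        for phase in PHASES:
            shift = lfc_rp.to_numpy() if (assay == "RP" and phase == "M") else 0.0
            cols = {}
            for r in range(config.n_rp_reps):
                depth = np.exp(rng.normal(0.0, config.depth_jitter_sd))
                mu = depth * 2.0 ** (base + shift)
                d = config.nb_dispersion
                cols[f"{assay}_{phase}_r{r + 1}"] = rng.negative_binomial(d, d / (d + mu))
            tables[(assay, phase)] = pd.DataFrame(cols, index=genes)

    for assay in ("PP", "PSS"):
        base = config.intensity_base + config.intensity_latent_scale * latent[assay].to_numpy()
        for phase in PHASES:
            shift = lfc_pp.to_numpy() if (assay == "PP" and phase == "M") else 0.0
            cols = {}
            for r in range(config.n_pp_reps):
                vals = base + shift + rng.normal(0.0, config.intensity_noise_sd, config.n_genes)
                p_detect = 1.0 / (
                    1.0 + np.exp(-(vals - config.missingness_midpoint) / config.missingness_scale)
                )
                vals = np.where(rng.random(config.n_genes) < p_detect, vals, np.nan)
                cols[f"{assay}_{phase}_r{r + 1}"] = vals
            tables[(assay, phase)] = pd.DataFrame(cols, index=genes)

    # non-specific (non-labelled) control arm: sparse low background
    ctl = {}
    for r in range(3):
        vals = rng.normal(18.5, 0.5, config.n_genes)
        vals = np.where(rng.random(config.n_genes) < 0.25, vals, np.nan)
        ctl[f"PP_control_r{r + 1}"] = vals
    pp_control = pd.DataFrame(ctl, index=genes)

    # footprint coverage rises with RP abundance
    log_mu_rp = config.base_log2_count + config.latent_sd * latent["RP"].to_numpy()
    cov = 1.0 / (1.0 + np.exp(-(log_mu_rp - 5.0) / 2.0))
    cov = np.clip(cov + rng.normal(0.0, 0.08, config.n_genes), 0.0, 1.0)
    coverage = pd.Series(cov, index=genes, name="coverage")

    truth = SyntheticTruth(de_genes=de_genes, lfc_rp=lfc_rp, lfc_pp=lfc_pp)
    return ExpressionStudy(tables, pp_control, coverage, latent, truth)


# ---------------------------------------------------------------------------
# toy transcriptome

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(
        _NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), n_codons - 1)
    )
    return "ATG" + body + "TAA"


def generate_toy_transcriptome(
    n_genes: int,
    paralog_pairs: int = 0,
    utr_edge_cases: bool = True,
    seed: int = 0,
) -> list[TranscriptRecord]:
    """A small annotated transcriptome exercising the assembly edge cases.

    When ``utr_edge_cases`` is set, the first transcripts include: a
    missing 5'UTR, a 3 nt 5'UTR, ORFs of length 1 and 2 (mod 3), and an
    ORF without a stop codon.  ``paralog_pairs`` gene pairs carry
    near-identical transcripts (<=2 mismatches) for multi-mapping tests.
    """
    if n_genes < 2 * paralog_pairs:
        raise ValueError("n_genes must allow 2 genes per paralog pair")
    rng = np.random.default_rng(seed)
    records: list[TranscriptRecord] = []

    def make(gi: int, **overrides) -> TranscriptRecord:
        orf = overrides.pop("orf_seq", None) or _random_orf(rng, int(rng.integers(40, 120)))
        from .reference import translate_orf

        rec = TranscriptRecord(
            transcript_id=f"T{gi:05d}",
            gene_id=f"G{gi:05d}",
            orf_seq=orf,
            utr5_seq=_random_seq(rng, int(rng.integers(20, 100))),
            utr3_seq=_random_seq(rng, int(rng.integers(20, 150))),
            flank5_seq=_random_seq(rng, 1000),
            flank3_seq=_random_seq(rng, 1000),
            ref_protein=translate_orf(orf).rstrip("*"),
        )
        for k, v in overrides.items():
            setattr(rec, k, v)
        return rec

    gi = 0
    if utr_edge_cases:
        records.append(make(gi, utr5_seq=None))  # missing 5'UTR
        gi += 1
        records.append(make(gi, utr5_seq=_random_seq(rng, 3)))  # 3 nt 5'UTR
        gi += 1
        for rem in (1, 2):  # ORF length 1 / 2 mod 3: stop lost, codon cut mid-way
            full = _random_orf(rng, int(rng.integers(40, 120)))
            rec = make(gi, orf_seq=full)
            rec.orf_seq = full[: len(full) - 3 - (3 - rem)]
            gi += 1
            records.append(rec)
        full = _random_orf(rng, int(rng.integers(40, 120)))
        records.append(make(gi, orf_seq=full[:-3]))  # no stop codon
        gi += 1

    for _ in range(paralog_pairs):
        a = make(gi)
        gi += 1
        seq = list(a.orf_seq)
        for pos in rng.choice(np.arange(3, len(seq) - 3), size=2, replace=False):
            cur = seq[pos]
            seq[pos] = rng.permuted([b for b in "ACGT" if b != cur])[0]
        b = make(gi, orf_seq="".join(seq))
        gi += 1
        records.extend([a, b])

    while gi < n_genes:
        records.append(make(gi))
        gi += 1
    return records


def write_transcriptome(records: list[TranscriptRecord], fasta_path, annot_path) -> None:
    """Write the component FASTA plus the annotation TSV.

    The FASTA stores per transcript the ``utr5+orf+utr3`` body and the
    two 1000 nt flanks as ``tid|flank5`` / ``tid|flank3``; lengths in the
    TSV give the split points.
    """
    with open(fasta_path, "w") as fh:
        for r in records:
            body = (r.utr5_seq or "") + r.orf_seq + (r.utr3_seq or "")
            fh.write(f">{r.transcript_id}\n{body}\n")
            fh.write(f">{r.transcript_id}|flank5\n{r.flank5_seq}\n")
            fh.write(f">{r.transcript_id}|flank3\n{r.flank3_seq}\n")
    rows = [
        {
            "transcript_id": r.transcript_id,
            "gene_id": r.gene_id,
            "utr5_len": len(r.utr5_seq or ""),
            "orf_len": len(r.orf_seq),
            "utr3_len": len(r.utr3_seq or ""),
            "ref_protein": r.ref_protein or "-",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(annot_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reads

# decoy contaminant fixtures: 5 rRNA-like and 5 tRNA-like sequences,
# regenerated deterministically from a fixed seed at import time
_DECOY_RNG = np.random.default_rng(20140530)
DECOY_CONTAMINANTS: dict[str, str] = {
    **{f"decoy_rRNA_{i}": _random_seq(_DECOY_RNG, 600) for i in range(1, 6)},
    **{f"decoy_tRNA_{i}": _random_seq(_DECOY_RNG, 80) for i in range(1, 6)},
}


def generate_reads(
    transcript_seqs: dict[str, str],
    abundance: dict[str, float] | pd.Series,
    n_reads: int,
    read_len: int = 51,
    adapter: str = DEFAULT_ADAPTER,
    contaminant_frac: float = 0.0,
    subst_rate: float = 0.001,
    seed: int = 0,
) -> list[Read]:
    """Simulate footprint reads: insert (24-35 nt) + adapter + padding.

    A ``contaminant_frac`` share of reads is drawn from the bundled decoy
    rRNA/tRNA sequences.  Each read records its ground-truth origin
    ``"tid:pos"`` (or ``"contaminant:name"``).  Substitution noise is
    applied to inserts at ``subst_rate`` per base.
    """
    if len(adapter) >= read_len:
        raise ValueError("adapter must be shorter than the read length")
    abund = pd.Series(abundance, dtype=float)
    if (abund < 0).any():
        raise ValueError("abundances must be nonnegative")
    abund = abund[abund > 0]
    rng = np.random.default_rng(seed)
    tids = list(abund.index)
    probs = (abund / abund.sum()).to_numpy()
    decoys = list(DECOY_CONTAMINANTS)

    reads = []
    for i in range(n_reads):
        contaminant = rng.random() < contaminant_frac
        if contaminant:
            name = decoys[rng.integers(0, len(decoys))]
            src = DECOY_CONTAMINANTS[name]
            origin = f"contaminant:{name}"
        else:
            tid = tids[rng.choice(len(tids), p=probs)]
            src = transcript_seqs[tid]
            origin = None  # filled below with position
        ins_len = int(rng.integers(24, 36))
        ins_len = min(ins_len, len(src))
        pos = int(rng.integers(0, len(src) - ins_len + 1))
        insert = list(src[pos : pos + ins_len])
        for j in range(len(insert)):
            if rng.random() < subst_rate:
                insert[j] = str(rng.permuted([b for b in "ACGT" if b != insert[j]])[0])
        if origin is None:
            origin = f"{tid}:{pos}"
        seq = "".join(insert) + adapter
        if len(seq) < read_len:
            seq += _random_seq(rng, read_len - len(seq))
        reads.append(Read(read_id=f"r{i:07d}", seq=seq[:read_len], origin=origin))
    return reads


def write_fastq(reads: list[Read], path) -> None:
    """Phred+33 FASTQ with constant high quality; origin in the header."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id} origin={r.origin}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


# ---------------------------------------------------------------------------
# PPI network and pathways


def generate_ppi(
    n_nodes: int,
    degree_exponent: float = 2.5,
    planted_module_sizes: tuple[int, ...] = (),
    seed: int = 0,
    min_degree: int = 3,
    max_degree: int | None = None,
    module_density: float = 0.3,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Configuration-model scale-free graph with planted connected modules.

    Degrees follow a discrete power law ``P(k) ~ k^-exponent`` on
    ``[min_degree, max_degree]``; self-loops and parallel edges are
    removed and the largest component retained.  The default minimum
    degree of 3 keeps the graph (and its degree-preserving rewirings)
    connected with high probability, emulating the dense PPI main
    component the analyses run on.  Each planted module is a node set
    made internally dense (edge probability ``module_density`` plus a
    connecting path), so it induces a connected subgraph.
    """
    if n_nodes <= sum(planted_module_sizes):
        raise ValueError("n_nodes must exceed the total planted module size")
    rng = np.random.default_rng(seed)
    if max_degree is None:
        max_degree = max(min_degree + 1, int(3 * np.sqrt(n_nodes)))
    support = np.arange(min_degree, max_degree + 1)
    pmf = support.astype(float) ** -degree_exponent
    degrees = rng.choice(support, size=n_nodes, p=pmf / pmf.sum())
    if degrees.sum() % 2:
        degrees[int(np.argmax(degrees == degrees.min()))] += 1

    g = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(g)  # collapse parallel edges
    g.remove_edges_from(nx.selfloop_edges(g))
    main = max(nx.connected_components(g), key=len)
    g = nx.relabel_nodes(g.subgraph(main).copy(), {n: f"G{n:05d}" for n in main})

    nodes = np.array(sorted(g.nodes))
    if sum(planted_module_sizes) > len(nodes):
        raise ValueError("main component too small for the planted modules; raise n_nodes")
    chosen = rng.choice(len(nodes), size=sum(planted_module_sizes), replace=False)
    modules = []
    offset = 0
    for size in planted_module_sizes:
        members = [str(n) for n in nodes[chosen[offset : offset + size]]]
        offset += size
        order = list(rng.permutation(members))
        for a, b in zip(order, order[1:]):  # connecting path
            g.add_edge(a, b)
        for i in range(size):
            for j in range(i + 1, size):
                if rng.random() < module_density:
                    g.add_edge(members[i], members[j])
        modules.append(set(members))

    truth = SyntheticTruth(planted_modules=modules)
    return g, truth


def degree_slope(g: nx.Graph, bin_ratio: float = 1.6) -> float:
    """Log-log slope of the degree distribution, on log-binned densities.

    Logarithmic binning pools the sparse single-count tail degrees so the
    least-squares slope is not dominated by their noise.
    """
    deg = np.array([d for _, d in g.degree if d > 0], dtype=float)
    edges = [deg.min()]
    while edges[-1] < deg.max():
        edges.append(edges[-1] * bin_ratio)
    edges = np.array(edges + [edges[-1] * bin_ratio])
    counts, _ = np.histogram(deg, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    ok = counts > 0
    density = counts[ok] / widths[ok]
    # weight by sqrt(count): near-empty tail bins carry little information
    return float(
        np.polyfit(np.log(centers[ok]), np.log(density), 1, w=np.sqrt(counts[ok]))[0]
    )


def generate_pathways(
    genes,
    n_pathways: int = 40,
    size_range: tuple[int, int] = (5, 40),
    planted: list[set] | None = None,
    seed: int = 0,
) -> dict[str, set]:
    """Random gene sets (GMT-style), optionally embedding planted modules."""
    rng = np.random.default_rng(seed)
    genes = np.array(sorted(genes))
    pathways = {}
    for i in range(n_pathways):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(len(genes), size=min(size, len(genes)), replace=False)
        pathways[f"PATH{i:03d}"] = {str(g) for g in genes[members]}
    for j, mod in enumerate(planted or []):
        pathways[f"PLANTED{j:02d}"] = set(mod)
    return pathways


def write_edge_list(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{a}\t{b}\n")
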
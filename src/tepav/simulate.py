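"""Seeded synthetic panels with known truth for every pipeline stage.

The generator emulates the statistical structure of a diversity panel of
inbred (effectively haploid) lines genotyped for annotated TE loci:

- per-TE population frequencies drawn from a U-shaped Beta mixture (most
  structural variants are either rare or nearly fixed);
- an age model tying LTR similarity to frequency: older insertions have
  had time to rise in frequency and to diverge their two LTRs, so
  expected similarity decreases monotonically with frequency;
- nested TEs placed inside outer elements, with presence conditioned on
  the outer element's presence (a nested copy cannot exist without its
  host) and a frequency at or below the host's;
- edge-window read counts that are Poisson around depth for present
  loci, Poisson around a small mismapping floor for absent loci, and a
  small fraction of genuinely uncertain entries at half depth;
- tag SNPs constructed at designed r2 by symmetric allele flipping, with
  the flip probability solved numerically from the expected-r2 curve.

Everything is driven by one integer seed and is byte-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .annotations import (
    ABSENT,
    PRESENT,
    CallMatrix,
    GeneModel,
    HomologGroup,
    TEAnnotation,
    write_bed,
    write_homolog_table,
)
from .coverage import SampleCoverage
from .ld import MarkerVector, ld_pair

_FAMILY_PREFIX = {"LTR": ("RLG", "RLC"), "TIR": ("DTA", "DTM"), "Helitron": ("DHH",)}
_ORDER_TO_GFF_TYPE = {
    "LTR": "LTR_retrotransposon",
    "TIR": "TIR_transposon",
    "Helitron": "helitron",
}


@dataclass
class AgeModel:
    """Monotone map frequency -> expected LTR similarity, plus noise.

    similarity = sim_max - sim_span * frequency + Normal(0, noise_sd),
    clipped to [0, 100]. With noise_sd = 0 the map is strictly monotone,
    which pins the Spearman correlation between similarity and frequency
    at -1 for LTRs.
    """

    sim_max: float = 100.0
    sim_span: float = 15.0
    noise_sd: float = 1.5


@dataclass
class CoverageModel:
    """Edge-window count regimes relative to sample depth.

    Present loci draw Poisson(depth * lambda_present_scale) per window,
    absent loci Poisson(depth * lambda_absent_scale) (mismapping noise),
    and an ``ambiguous_fraction`` of entries draw from the midpoint
    regime Poisson(depth / 2) to create genuinely uncertain cases.
    ``overdispersion`` > 0 switches to negative-binomial noise with that
    gamma-mixing variance inflation, for stress tests.
    """

    lambda_present_scale: float = 1.0
    lambda_absent_scale: float = 0.02
    ambiguous_fraction: float = 0.02
    overdispersion: float = 0.0


@dataclass
class GenomeLayout:
    n_chromosomes: int = 2
    gap_range: tuple[int, int] = (500, 5000)
    te_length_range: tuple[int, int] = (1500, 12000)
    gene_length_range: tuple[int, int] = (2000, 6000)
    gene_every: int = 5  # one gene after every N outer TEs


@dataclass
class SimConfig:
    """All knobs of the generator; ``seed`` is mandatory."""

    seed: int
    n_samples: int = 200
    n_tes: int = 2000
    order_mix: Mapping[str, float] = field(
        default_factory=lambda: {"LTR": 0.7, "TIR": 0.2, "Helitron": 0.1}
    )
    freq_beta: tuple[float, float] = (0.5, 0.5)
    age_model: AgeModel = field(default_factory=AgeModel)
    nesting_rate: float = 0.10
    coverage_model: CoverageModel = field(default_factory=CoverageModel)
    depth: float = 30.0
    depth_jitter: float = 0.1  # per-sample uniform depth spread, +/- fraction
    ld_targets: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    layout: GenomeLayout = field(default_factory=GenomeLayout)
    assembly: str = "sim1"
    n_families_per_order: int = 25

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        total = sum(self.order_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"order_mix proportions sum to {total}, not 1")
        if not 0.0 <= self.nesting_rate < 1.0:
            raise ValueError("nesting_rate must be in [0, 1)")


@dataclass
class TruthPanel:
    """A simulated panel with full truth attached."""

    config: SimConfig
    tes: list[TEAnnotation]
    genes: list[GeneModel]
    sample_ids: list[str]
    truth_calls: CallMatrix  # present/absent only
    te_meta: pd.DataFrame  # indexed by te_id; includes assigned + realized freq
    chrom_lengths: dict[str, int]
    regions: pd.DataFrame  # synthetic low-recombination intervals
    homolog_groups: list[HomologGroup]

    @property
    def presence(self) -> pd.DataFrame:
        """Truth calls as a 0/1 frame (tes x samples)."""
        return (self.truth_calls.labels == PRESENT).astype(int)

    @property
    def true_frequencies(self) -> pd.Series:
        return self.te_meta["frequency"]


def simulate_truth_panel(config: SimConfig) -> TruthPanel:
    """Draw a complete panel: annotations, genes, truth calls, metadata."""
    rng = np.random.default_rng(config.seed)
    lay = config.layout
    orders = list(config.order_mix)
    probs = np.array([config.order_mix[o] for o in orders], dtype=float)

    n_nested = int(round(config.n_tes * config.nesting_rate))
    n_outer = config.n_tes - n_nested
    if n_nested > n_outer:
        raise ValueError("nesting_rate infeasible: more nested than outer TEs")

    family_pool = {
        order: [
            f"{rng.choice(_FAMILY_PREFIX[order])}{i:05d}"
            for i in range(1, config.n_families_per_order + 1)
        ]
        for order in orders
    }
    # Zipf-ish family sizes
    family_w = {
        order: (w := 1.0 / np.arange(1, config.n_families_per_order + 1)) / w.sum()
        for order in orders
    }

    tes: list[TEAnnotation] = []
    genes: list[GeneModel] = []
    chrom_cursor = {f"chr{i + 1}": 1 for i in range(lay.n_chromosomes)}
    chroms = list(chrom_cursor)

    def draw_family(order: str) -> str:
        return str(rng.choice(family_pool[order], p=family_w[order]))

    # --- outer TEs and genes along the chromosomes
    p_assigned: dict[str, float] = {}
    for i in range(n_outer):
        chrom = chroms[i % len(chroms)]
        gap = int(rng.integers(*lay.gap_range))
        length = int(rng.integers(*lay.te_length_range))
        start = chrom_cursor[chrom] + gap
        end = start + length - 1
        chrom_cursor[chrom] = end
        order = str(rng.choice(orders, p=probs))
        family = draw_family(order)
        te_id = f"{config.assembly}_te{i:05d}"
        tes.append(
            TEAnnotation(
                te_id=te_id,
                assembly=config.assembly,
                chrom=chrom,
                start=start,
                end=end,
                order=order,
                superfamily=family[:3],
                family=family,
            )
        )
        p_assigned[te_id] = float(rng.beta(*config.freq_beta))
        if (i + 1) % lay.gene_every == 0:
            gchrom = chrom
            ggap = int(rng.integers(*lay.gap_range))
            glen = int(rng.integers(*lay.gene_length_range))
            gstart = chrom_cursor[gchrom] + ggap
            gend = gstart + glen - 1
            chrom_cursor[gchrom] = gend
            genes.append(
                _random_gene(rng, f"gene{len(genes):04d}", gchrom, gstart, gend)
            )

    # --- nested TEs inside sufficiently long hosts
    hosts = [te for te in tes if te.length >= 2000]
    if n_nested > len(hosts):
        raise ValueError("nesting_rate infeasible for this genome layout")
    host_idx = rng.choice(len(hosts), size=n_nested, replace=False)
    for j, hi in enumerate(host_idx):
        host = hosts[int(hi)]
        max_len = host.length - 200
        length = int(rng.integers(300, min(max_len, 5000)))
        offset = int(rng.integers(50, host.length - length - 50))
        start = host.start + offset
        end = start + length - 1
        order = str(rng.choice(orders, p=probs))
        family = draw_family(order)
        te_id = f"{config.assembly}_nte{j:05d}"
        tes.append(
            TEAnnotation(
                te_id=te_id,
                assembly=config.assembly,
                chrom=host.chrom,
                start=start,
                end=end,
                order=order,
                superfamily=family[:3],
                family=family,
                nested_in=host.te_id,
            )
        )
        # nested insertion is younger than its host: frequency at or below
        p_assigned[te_id] = p_assigned[host.te_id] * float(rng.uniform(0.3, 1.0))

    chrom_lengths = {c: cur + 20_000 for c, cur in chrom_cursor.items()}

    # --- truth calls
    sample_ids = [f"line{i:03d}" for i in range(config.n_samples)]
    te_ids = [te.te_id for te in tes]
    by_id = {te.te_id: te for te in tes}
    presence = np.zeros((len(tes), config.n_samples), dtype=bool)
    row_of = {tid: i for i, tid in enumerate(te_ids)}
    for te in tes:
        if te.nested_in is None:
            presence[row_of[te.te_id]] = rng.random(config.n_samples) < p_assigned[te.te_id]
    for te in tes:
        if te.nested_in is not None:
            outer_row = presence[row_of[te.nested_in]]
            p_out = p_assigned[te.nested_in]
            cond = p_assigned[te.te_id] / p_out if p_out > 0 else 0.0
            presence[row_of[te.te_id]] = outer_row & (
                rng.random(config.n_samples) < cond
            )
    labels = pd.DataFrame(
        np.where(presence, PRESENT, ABSENT), index=pd.Index(te_ids, name="te_id"),
        columns=pd.Index(sample_ids, name="sample_id"),
    )
    truth_calls = CallMatrix(labels)
    realized_freq = presence.mean(axis=1)

    # --- LTR similarity from the age model
    age = config.age_model
    sims: list[float | None] = []
    for i, te in enumerate(tes):
        if te.order != "LTR":
            sims.append(None)
            continue
        s = age.sim_max - age.sim_span * p_assigned[te.te_id]
        if age.noise_sd > 0:
            s += float(rng.normal(0.0, age.noise_sd))
        te.ltr_similarity = float(np.clip(s, 0.0, 100.0))
        sims.append(te.ltr_similarity)

    te_meta = pd.DataFrame(
        {
            "chrom": [te.chrom for te in tes],
            "start": [te.start for te in tes],
            "end": [te.end for te in tes],
            "order": [te.order for te in tes],
            "family": [te.family for te in tes],
            "ltr_similarity": [s if s is not None else np.nan for s in sims],
            "nested_in": [te.nested_in for te in tes],
            "p_assigned": [p_assigned[t] for t in te_ids],
            "frequency": realized_freq,
        },
        index=pd.Index(te_ids, name="te_id"),
    )

    # middle third of each chromosome stands in for the low-recombination
    # pericentromeric interval
    regions = pd.DataFrame(
        [
            {"chrom": c, "start": length // 3, "end": 2 * length // 3}
            for c, length in chrom_lengths.items()
        ]
    )

    # each TE belongs to 1-4 pseudo-assemblies; member ids are suffixed
    pseudo = ["asmA", "asmB", "asmC", "asmD"]
    groups = []
    n_members = rng.integers(1, 5, size=len(te_ids))
    for tid, k in zip(te_ids, n_members):
        members = [(pseudo[m], f"{tid}@{pseudo[m]}") for m in range(int(k))]
        groups.append(
            HomologGroup(
                nonredundant_id=f"nr_{tid}", members=members, source_assembly="asmA"
            )
        )

    return TruthPanel(
        config=config,
        tes=tes,
        genes=genes,
        sample_ids=sample_ids,
        truth_calls=truth_calls,
        te_meta=te_meta,
        chrom_lengths=chrom_lengths,
        regions=regions,
        homolog_groups=groups,
    )


def _random_gene(rng, gene_id: str, chrom: str, start: int, end: int) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(1, 4))
    length = end - start + 1
    if n_exons == 1 or length < 900:
        exons = [(start, end)]
    else:
        cuts = np.sort(rng.choice(np.arange(1, length - 1), size=2 * (n_exons - 1), replace=False))
        exons = []
        pos = start
        for k in range(n_exons - 1):
            e = start + int(cuts[2 * k])
            exons.append((pos, e))
            pos = start + int(cuts[2 * k + 1]) + 1
        exons.append((pos, end))
        exons = [iv for iv in exons if iv[1] >= iv[0]]
    utr_len = min(150, (exons[0][1] - exons[0][0]) // 2 + 1)
    if strand == "+":
        utr5 = [(exons[0][0], exons[0][0] + utr_len - 1)]
        utr3 = [(exons[-1][1] - utr_len + 1, exons[-1][1])]
    else:
        utr5 = [(exons[-1][1] - utr_len + 1, exons[-1][1])]
        utr3 = [(exons[0][0], exons[0][0] + utr_len - 1)]
    return GeneModel(
        gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand,
        exons=exons, utr5=utr5, utr3=utr3,
    )


# ---------------------------------------------------------------------------
# Coverage features


def simulate_features(
    panel: TruthPanel,
    depth: float | None = None,
    coverage_model: CoverageModel | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Edge-window counts for every (TE, sample), plus realized depths.

    Returns a long feature frame (te_id, sample_id, start_cov, end_cov,
    order) and a sample -> realized depth map. Per-sample depth jitters
    uniformly within +/- ``config.depth_jitter`` of the nominal depth.
    """
    cfg = panel.config
    depth = cfg.depth if depth is None else depth
    cm = coverage_model or cfg.coverage_model
    rng = np.random.default_rng(seed)
    n_tes, n_samples = len(panel.tes), len(panel.sample_ids)

    sample_depth = depth * rng.uniform(
        1.0 - cfg.depth_jitter, 1.0 + cfg.depth_jitter, size=n_samples
    )
    present = panel.presence.to_numpy(dtype=bool)
    lam = np.where(
        present,
        cm.lambda_present_scale,
        cm.lambda_absent_scale,
    ) * sample_depth[None, :]
    if cm.ambiguous_fraction > 0:
        fuzzy = rng.random((n_tes, n_samples)) < cm.ambiguous_fraction
        lam = np.where(fuzzy, sample_depth[None, :] / 2.0, lam)
    if cm.overdispersion > 0:
        shape = 1.0 / cm.overdispersion
        lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
    start_cov = rng.poisson(lam).astype(float)
    end_cov = rng.poisson(lam).astype(float)

    te_ids = np.repeat([te.te_id for te in panel.tes], n_samples)
    orders = np.repeat([te.order for te in panel.tes], n_samples)
    samples = np.tile(panel.sample_ids, n_tes)
    features = pd.DataFrame(
        {
            "te_id": te_ids,
            "sample_id": samples,
            "start_cov": start_cov.ravel(),
            "end_cov": end_cov.ravel(),
            "order": orders,
        }
    )
    coverages = dict(zip(panel.sample_ids, sample_depth.astype(float)))
    return features, coverages


# ---------------------------------------------------------------------------
# Designed-LD tag SNPs


def expected_r2(p: float, q: float) -> float:
    """Population r2 between a 0/1 vector of frequency p and its copy with
    symmetric flip probability q."""
    py = q + p * (1.0 - 2.0 * q)
    vy = py * (1.0 - py)
    if vy == 0:
        return 0.0
    return (1.0 - 2.0 * q) ** 2 * p * (1.0 - p) / vy


def solve_flip_probability(p: float, target_r2: float) -> float:
    """Flip probability achieving an expected r2 of ``target_r2``.

    The closed form of r2 depends on allele frequency, so the inverse is
    found by root-finding on [0, 0.5]; this function is also the oracle
    documented for the tag-SNP design.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"TE frequency {p} monomorphic; no tag SNP possible")
    if not 0.0 <= target_r2 <= 1.0:
        raise ValueError(f"target r2 {target_r2} outside [0, 1]")
    if target_r2 == 1.0:
        return 0.0
    if target_r2 == 0.0:
        return 0.5
    return float(brentq(lambda q: expected_r2(p, q) - target_r2, 0.0, 0.5, xtol=1e-12))


def simulate_tag_snps(
    panel: TruthPanel,
    ld_targets: Sequence[float] | None = None,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.2, 0.8),
    n_background: int = 0,
    position_spread: int = 100_000,
) -> tuple[list[MarkerVector], pd.DataFrame]:
    """Design one tag SNP per target r2, each tied to a random TE.

    The SNP starts as a copy of the TE's presence vector and each allele
    is flipped with the probability solved from the expected-r2 curve;
    ``target = 0`` draws an independent SNP at the same frequency.
    Optionally ``n_background`` unlinked SNPs are scattered per designed
    SNP's window. Infeasible designs (monomorphic partner or monomorphic
    flipped vector) are reported in the design table and skipped.
    """
    cfg = panel.config
    targets = list(cfg.ld_targets if ld_targets is None else ld_targets)
    rng = np.random.default_rng(seed)
    freq = panel.true_frequencies
    candidates = freq[(freq >= maf_range[0]) & (freq <= maf_range[1])].index.to_list()
    if len(candidates) < len(targets):
        raise ValueError("not enough polymorphic TEs for the requested targets")
    chosen = rng.choice(len(candidates), size=len(targets), replace=False)
    by_id = {te.te_id: te for te in panel.tes}
    presence = panel.presence

    markers: list[MarkerVector] = []
    design_rows = []
    snp_counter = 0
    for target, ci in zip(targets, chosen):
        te_id = candidates[int(ci)]
        te = by_id[te_id]
        x = presence.loc[te_id].to_numpy(dtype=float)
        p = float(x.mean())
        status = "ok"
        q = np.nan
        realized = np.nan
        snp_id = f"snp{snp_counter:05d}"
        snp_counter += 1
        pos = te.midpoint + int(rng.integers(-position_spread, position_spread + 1))
        pos = max(1, pos)
        if target == 0.0:
            y = (rng.random(x.size) < p).astype(float)
        else:
            q = solve_flip_probability(p, target)
            flips = rng.random(x.size) < q
            y = np.where(flips, 1.0 - x, x)
        if y.min() == y.max():
            status = "monomorphic"
            design_rows.append(
                {
                    "snp_id": snp_id, "te_id": te_id, "target_r2": target,
                    "flip_prob": q, "realized_r2": np.nan, "status": status,
                }
            )
            continue
        marker = MarkerVector(snp_id, te.chrom, pos, y)
        te_vec = MarkerVector(te_id, te.chrom, te.midpoint, x)
        res = ld_pair(te_vec, marker)
        realized = res.r2 if res.defined else np.nan
        markers.append(marker)
        design_rows.append(
            {
                "snp_id": snp_id, "te_id": te_id, "target_r2": target,
                "flip_prob": q, "realized_r2": realized, "status": status,
            }
        )
        for _ in range(n_background):
            bg_id = f"snp{snp_counter:05d}"
            snp_counter += 1
            bg_p = float(rng.uniform(0.1, 0.9))
            bg = (rng.random(x.size) < bg_p).astype(float)
            if bg.min() == bg.max():
                continue
            bg_pos = max(1, te.midpoint + int(rng.integers(-900_000, 900_001)))
            markers.append(MarkerVector(bg_id, te.chrom, bg_pos, bg))
            design_rows.append(
                {
                    "snp_id": bg_id, "te_id": te_id, "target_r2": np.nan,
                    "flip_prob": np.nan, "realized_r2": np.nan,
                    "status": "background",
                }
            )
    skipped = [r for r in design_rows if r["status"] == "monomorphic"]
    if skipped:
        warnings.warn(f"{len(skipped)} designed tag SNPs infeasible and skipped")
    return markers, pd.DataFrame(design_rows)


# ---------------------------------------------------------------------------
# Fixture export


def export_fixture(
    panel: TruthPanel,
    features: pd.DataFrame | None,
    snps: Sequence[MarkerVector] | None,
    outdir: str | Path,
    coverages: Mapping[str, float] | None = None,
) -> dict[str, Path]:
    """Write the panel as on-disk files so the file-based interface can be
    exercised end to end: GFF3 (TEs, genes), TSV (truth calls, features,
    homolog table, coverages), VCF (SNPs) and BED (regions)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["tes"] = outdir / "tes.gff3"
    with open(paths["tes"], "w") as fh:
        fh.write("##gff-version 3\n")
        for te in panel.tes:
            attrs = [f"ID={te.te_id}", f"fam={te.family}", f"sup={te.superfamily}"]
            if te.ltr_similarity is not None:
                attrs.append(f"ltr_identity={te.ltr_similarity / 100.0:.6f}")
            if te.nested_in is not None:
                attrs.append(f"nested_in={te.nested_in}")
            fh.write(
                "\t".join(
                    [
                        te.chrom, "tepav_sim", _ORDER_TO_GFF_TYPE[te.order],
                        str(te.start), str(te.end), ".", "+", ".", ";".join(attrs),
                    ]
                )
                + "\n"
            )

    paths["genes"] = outdir / "genes.gff3"
    with open(paths["genes"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in panel.genes:
            def _line(ftype, s, e, attrs):
                return "\t".join(
                    [g.chrom, "tepav_sim", ftype, str(s), str(e), ".", g.strand, ".", attrs]
                ) + "\n"
            fh.write(_line("gene", g.start, g.end, f"ID={g.gene_id}"))
            mrna = f"{g.gene_id}.t1"
            fh.write(_line("mRNA", g.start, g.end, f"ID={mrna};Parent={g.gene_id}"))
            for k, (s, e) in enumerate(g.exons):
                fh.write(_line("exon", s, e, f"ID={mrna}.e{k};Parent={mrna}"))
            for k, (s, e) in enumerate(g.utr5):
                fh.write(_line("five_prime_UTR", s, e, f"ID={mrna}.u5{k};Parent={mrna}"))
            for k, (s, e) in enumerate(g.utr3):
                fh.write(_line("three_prime_UTR", s, e, f"ID={mrna}.u3{k};Parent={mrna}"))

    paths["truth_calls"] = outdir / "truth_calls.tsv"
    panel.truth_calls.write(paths["truth_calls"])

    paths["te_meta"] = outdir / "te_meta.tsv"
    panel.te_meta.to_csv(paths["te_meta"], sep="\t")

    paths["homolog"] = outdir / "homolog.tsv"
    write_homolog_table(panel.homolog_groups, paths["homolog"])

    paths["regions"] = outdir / "regions.bed"
    write_bed(panel.regions, paths["regions"])

    if features is not None:
        paths["features"] = outdir / "features.tsv"
        features.to_csv(paths["features"], sep="\t", index=False)

    if coverages is not None:
        paths["coverages"] = outdir / "coverages.tsv"
        pd.Series(coverages, name="realized_depth").rename_axis("sample_id").to_csv(
            paths["coverages"], sep="\t"
        )

    if snps is not None:
        paths["snps"] = outdir / "snps.vcf"
        _write_vcf(snps, panel.sample_ids, panel.chrom_lengths, paths["snps"])
    return paths


def _write_vcf(
    snps: Sequence[MarkerVector],
    sample_ids: Sequence[str],
    chrom_lengths: Mapping[str, int],
    path: Path,
) -> None:
    # inbred lines: 0/1 codes written as homozygous diploid genotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for snp in sorted(snps, key=lambda s: (s.chrom, s.position)):
            gts = [
                "./."
                if np.isnan(a)
                else ("1/1" if a == 1.0 else "0/0")
                for a in snp.alleles
            ]
            fh.write(
                f"{snp.chrom}\t{snp.position}\t{snp.marker_id}\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
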
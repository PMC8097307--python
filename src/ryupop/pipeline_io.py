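"""File formats, configuration and end-to-end pipeline orchestration.

Consumes and produces the field's plain-text formats: VCF v4.2 (GT only),
two-column sample-to-population TSV (with header), 3-column genetic maps
(chrom, bp, cM) or PLINK .map, and TSV/JSON result tables.  Every output
table carries a comment line with the configuration hash and seed so that
artifacts are traceable and bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ibd as ibd_mod
from . import ne_inference, popgen_stats, qc as qc_mod
from .coalescent_sim import (
    HaplotypePanel,
    simulate_pairwise_ibd,
    simulate_sites,
)
from .demographic_model import build_fitted_model
from .qc import GenotypeMatrix

logger = logging.getLogger("ryupop")

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_labels",
    "write_labels",
    "write_genetic_map",
    "PipelineConfig",
    "run_pipeline",
]


# ----------------------------------------------------------------------- VCF I/O

def write_vcf(panel_or_matrix, path) -> None:
    """Write a phased panel (GT ``a|b``) or genotype matrix (GT ``a/b``)."""
    is_panel = isinstance(panel_or_matrix, HaplotypePanel)
    obj = panel_or_matrix
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = obj.samples
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        if is_panel:
            H = obj.haplotypes
            for j in range(obj.n_sites):
                gts = "\t".join(
                    f"{H[2 * i, j]}|{H[2 * i + 1, j]}" for i in range(obj.n_samples)
                )
                fh.write(
                    f"{obj.chrom}\t{obj.pos_bp[j]}\tsnp{j}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
                )
        else:
            G = obj.genotypes
            chrom = obj.chrom if obj.chrom is not None else ["1"] * obj.n_sites
            pos = obj.pos if obj.pos is not None else np.arange(1, obj.n_sites + 1)
            code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
            for j in range(obj.n_sites):
                gts = "\t".join(code[int(G[i, j])] for i in range(obj.n_samples))
                fh.write(f"{chrom[j]}\t{pos[j]}\tsnp{j}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, populations: dict[str, str] | None = None):
    """Read biallelic SNPs from a VCF with GT.

    Returns a :class:`HaplotypePanel` when every genotype is phased and
    called, otherwise a :class:`GenotypeMatrix` (with a warning when phasing
    is mixed).  Non-biallelic records are skipped and counted; the skip count
    is attached to the returned object as ``n_skipped``.  Genetic positions
    default to 1 cM/Mb and can be re-assigned from a map downstream.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    pos = []
    chroms = []
    n_skipped = 0
    all_phased = True
    any_missing = False
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1 or var.is_indel:
            n_skipped += 1
            continue
        gts = var.genotypes  # [a0, a1, phased]
        site = []
        for g in gts:
            if len(g) < 3:
                raise ValueError(f"malformed GT at record {i + 1} ({var.CHROM}:{var.POS})")
            a0, a1, phased = g[0], g[1], g[-1]
            if a0 < 0 or a1 < 0:
                any_missing = True
            elif not phased:
                all_phased = False
            site.append((a0, a1))
        rows.append(site)
        pos.append(var.POS)
        chroms.append(var.CHROM)
    if not rows:
        raise ValueError(f"no usable biallelic SNPs in {path}")
    arr = np.array(rows, dtype=np.int16)  # (n_sites, n_samples, 2)
    pops = [populations.get(s, "NA") for s in samples] if populations else ["NA"] * len(samples)

    if all_phased and not any_missing:
        hap = np.empty((2 * len(samples), len(pos)), dtype=np.int8)
        hap[0::2, :] = arr[:, :, 0].T
        hap[1::2, :] = arr[:, :, 1].T
        panel = HaplotypePanel(
            samples=samples,
            populations=pops,
            haplotypes=hap,
            pos_bp=np.asarray(pos, dtype=np.int64),
            pos_cM=np.asarray(pos, dtype=np.float64) / 1e6,
            chrom=str(chroms[0]),
        )
        panel.n_skipped = n_skipped
        return panel

    if not all_phased and not any_missing:
        warnings.warn(
            "VCF contains unphased genotypes; returning a genotype matrix",
            stacklevel=2,
        )
    g = np.where(
        (arr[:, :, 0] < 0) | (arr[:, :, 1] < 0),
        -1,
        arr[:, :, 0] + arr[:, :, 1],
    ).T.astype(np.int8)
    matrix = GenotypeMatrix(
        genotypes=g,
        samples=samples,
        populations=pops,
        chrom=np.asarray(chroms),
        pos=np.asarray(pos, dtype=np.int64),
    )
    matrix.n_skipped = n_skipped
    return matrix


# ------------------------------------------------------------------- label / map

def write_labels(samples: list[str], populations: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for s, p in zip(samples, populations):
            fh.write(f"{s}\t{p}\n")


def read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "population" not in df.columns:
        raise ValueError("label TSV must have a 'sample_id\\tpopulation' header")
    return dict(zip(df["sample_id"], df["population"]))


def write_genetic_map(panel: HaplotypePanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tbp\tcM\n")
        for bp, cm in zip(panel.pos_bp, panel.pos_cM):
            fh.write(f"{panel.chrom}\t{bp}\t{cm:.6f}\n")


# ------------------------------------------------------------------ configuration

@dataclass
class PipelineConfig:
    """Declarative end-to-end pipeline configuration.

    When ``simulate`` is set the input panel is generated under the fitted
    island model (with optional parameter overrides); otherwise ``vcf``,
    ``labels`` and optionally ``genetic_map`` paths are read.
    """

    out_dir: str
    seed: int = 1
    # either simulate ...
    simulate: bool = True
    model_overrides: dict = field(default_factory=dict)
    sample_sizes: dict = field(
        default_factory=lambda: {"CHB": 20, "OKI": 20, "MYNE": 20, "MYSW": 20, "IKM": 20}
    )
    n_sites: int = 20_000
    # ... or read
    vcf: str | None = None
    labels: str | None = None
    genetic_map: str | None = None
    # analysis settings
    fst_pairs: list = field(default_factory=lambda: [["MYNE", "IKM"], ["MYSW", "IKM"]])
    dstat_quadruples: list = field(
        default_factory=lambda: [["CHB", "OKI", "IKM", "MYNE"]]
    )
    ibd_min_cM: float = 6.0
    ibd_seed_sites: int = 64
    ibd_merge_gap_cM: float = 0.6
    ne_G: int = 50
    ne_smoothing: float = 5.0
    ne_deme: str = "IKM"
    ne_n_pairs: int = 300
    ne_genome_cM: float = 3000.0
    roh: bool = True
    pca_components: int = 2

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis settings (the output path does not matter)."""
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> str:
    return f"config={config.config_hash()} seed={config.seed}"


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute simulate/read -> QC -> statistics -> IBD -> Ne fit.

    Every artifact is written under ``config.out_dir`` with a provenance
    comment; a failure in one stage halts the run with the stage name while
    earlier artifacts remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    stage = "input"
    log_lines = [f"# {prov}"]
    try:
        if config.simulate:
            model = build_fitted_model(**config.model_overrides)
            panel = simulate_sites(
                model, config.sample_sizes, config.n_sites, seed=config.seed
            )
            write_vcf(panel, out / "panel.vcf")
            write_labels(panel.samples, panel.populations, out / "labels.tsv")
            write_genetic_map(panel, out / "map.tsv")
        else:
            if config.vcf is None or config.labels is None:
                raise ValueError("vcf and labels paths required when simulate=false")
            for p in (config.vcf, config.labels, config.genetic_map):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")
            labels = read_labels(config.labels)
            panel = read_vcf(config.vcf, populations=labels)
            if config.genetic_map is not None and isinstance(panel, HaplotypePanel):
                gmap = ibd_mod.GeneticMap.from_file(config.genetic_map)
                panel.pos_cM = np.asarray(
                    gmap.bp_to_cM(panel.chrom, panel.pos_bp), dtype=np.float64
                )
        log_lines.append(f"input: {panel.n_samples} samples x {panel.n_sites} sites")

        stage = "qc"
        matrix = GenotypeMatrix.from_panel(panel)
        filtered, report = qc_mod.apply_qc(matrix)
        report.insert(0, "provenance", prov)
        report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        log_lines.append(f"qc: {filtered.n_samples} samples x {filtered.n_sites} sites")

        stage = "fst"
        rows = []
        for pa, pb in config.fst_pairs:
            r = popgen_stats.hudson_fst_from_panel(panel, pa, pb)
            rows.append((pa, pb, r.fst, r.se, r.n_loci, r.n_blocks))
        pd.DataFrame(
            rows, columns=["pop1", "pop2", "fst", "se", "n_loci", "n_blocks"]
        ).to_csv(out / "fst.tsv", sep="\t", index=False)

        stage = "dstat"
        rows = []
        for quad in config.dstat_quadruples:
            r = popgen_stats.patterson_d_from_panel(panel, tuple(quad))
            rows.append((*quad, r.d, r.z, r.se, r.n_blocks))
        pd.DataFrame(
            rows, columns=["p1", "p2", "p3", "p4", "d", "z", "se", "n_blocks"]
        ).to_csv(out / "dstat.tsv", sep="\t", index=False)

        stage = "sfs"
        sfs = popgen_stats.joint_sfs_from_panel(panel)
        sfs.to_json(out / "sfs.json")

        stage = "roh"
        if config.roh:
            geno = panel.genotypes()
            rows = []
            for i, s in enumerate(panel.samples):
                segs = popgen_stats.roh_detect(
                    geno[i], panel.pos_bp, sample=s, chrom=panel.chrom
                )
                rows.append((s, panel.populations[i], popgen_stats.total_roh(segs), len(segs)))
            pd.DataFrame(
                rows, columns=["sample", "population", "total_roh_bp", "n_segments"]
            ).to_csv(out / "roh.tsv", sep="\t", index=False)

        stage = "pca"
        scores = popgen_stats.pca_projection(
            panel.genotypes(), k=config.pca_components
        )
        pd.DataFrame(
            scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
        ).assign(sample=panel.samples, population=panel.populations).to_csv(
            out / "pca.tsv", sep="\t", index=False
        )

        stage = "ibd"
        segments = ibd_mod.detect_ibd(
            panel, min_cM=config.ibd_min_cM, seed_sites=config.ibd_seed_sites
        )
        segments = ibd_mod.merge_segments(
            segments, max_gap_cM=config.ibd_merge_gap_cM, panel=panel
        )
        ibd_mod.write_segments_tsv(segments, out / "ibd_segments.tsv", provenance=prov)

        stage = "share"
        pops = sorted(set(panel.populations))
        rows = []
        for i, pa in enumerate(pops):
            for pb in pops[i:]:
                sa = [s for s, p in zip(panel.samples, panel.populations) if p == pa]
                sb = [s for s, p in zip(panel.samples, panel.populations) if p == pb]
                if pa == pb and len(sa) < 2:
                    continue
                r = ibd_mod.sharing_index(segments, sa, sb, pop_i=pa, pop_j=pb)
                rows.append((pa, pb, r.n, r.m, r.index, r.n_pairs))
        pd.DataFrame(
            rows, columns=["pop_i", "pop_j", "n", "m", "index", "n_pairs"]
        ).to_csv(out / "sharing_index.tsv", sep="\t", index=False)

        stage = "nefit"
        model = build_fitted_model(**config.model_overrides)
        truth = simulate_pairwise_ibd(
            model,
            config.ne_deme,
            config.ne_n_pairs,
            config.ne_genome_cM,
            seed=config.seed + 1,
            min_emit_cM=config.ibd_min_cM,
        )
        spec = ne_inference.spectrum_from_segments(
            truth,
            n_pairs=config.ne_n_pairs,
            genome_length_cM=config.ne_genome_cM,
            min_cM=config.ibd_min_cM,
        )
        traj = ne_inference.fit_ne(spec, G=config.ne_G, smoothing=config.ne_smoothing)
        traj.to_tsv(out / "ne_trajectory.tsv", provenance=prov)
        log_lines.append(
            f"nefit: converged={traj.converged} "
            f"harmonic_mean={len(traj.ne) / np.sum(1.0 / traj.ne):.0f}"
        )
    except Exception as exc:
        (out / "pipeline.log").write_text(
            "\n".join(log_lines + [f"FAILED at stage {stage}: {exc}"]) + "\n"
        )
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "pipeline.log").write_text("\n".join(log_lines + ["done"]) + "\n")
    return out
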
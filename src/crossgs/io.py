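"""Text-format import/export: VCF, genotype matrices, effect tables.

Physical coordinates in exported VCFs follow the 1 cM ~ 1 Mb convention:
``POS = round(position_in_Morgans * 1e8)`` base pairs on contig "1".
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .genome import GeneticMap
from .lasso import MarkerEstimates
from .population import Population
from .trait import TraitArchitecture

__all__ = [
    "morgans_to_bp",
    "write_vcf",
    "read_vcf_genotypes",
    "write_genotype_matrix",
    "write_architecture",
    "read_architecture",
    "write_estimates",
    "read_phenotypes",
    "write_manifest",
    "read_manifest",
]

BP_PER_MORGAN = 100_000_000  # 1 cM ~ 1 Mb


def morgans_to_bp(positions: np.ndarray) -> np.ndarray:
    bp = np.round(np.asarray(positions) * BP_PER_MORGAN).astype(np.int64)
    # VCF positions are 1-based and must be unique on the contig
    bp = np.maximum(bp, 1)
    for i in range(1, bp.size):
        if bp[i] <= bp[i - 1]:
            bp[i] = bp[i - 1] + 1
    return bp


def write_vcf(path: str | Path, pop: Population, gmap: GeneticMap,
              loci: np.ndarray | None = None) -> None:
    """Write phased genotypes to an uncompressed VCF."""
    idx = np.arange(gmap.n_loci) if loci is None else np.asarray(loci)
    pos_bp = morgans_to_bp(gmap.positions[idx])
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID=1,length={BP_PER_MORGAN + idx.size + 1}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    samples = [f"{pop.breed}_{i}" for i in pop.ids]
    for s in samples:
        header.add_sample(s)
    haps = pop.haplotypes[:, :, idx]
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for k, j in enumerate(idx):
            rec = vcf.new_record(contig="1", start=int(pos_bp[k]) - 1,
                                 alleles=("A", "B"), id=f"locus{j}")
            for s_i, s in enumerate(samples):
                rec.samples[s]["GT"] = (int(haps[s_i, 0, k]),
                                        int(haps[s_i, 1, k]))
                rec.samples[s].phased = True
            vcf.write(rec)


def read_vcf_genotypes(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read phased genotypes back: (haplotypes (n,2,L), positions_bp, samples)."""
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        haps: list[np.ndarray] = []
        pos: list[int] = []
        for rec in vcf:
            gt = np.array([rec.samples[s]["GT"] for s in samples],
                          dtype=np.uint8)
            haps.append(gt)
            pos.append(rec.pos)
    return (np.stack(haps, axis=2) if haps else np.empty((len(samples), 2, 0), np.uint8),
            np.asarray(pos, dtype=np.int64), samples)


def write_genotype_matrix(path: str | Path, pop: Population,
                          loci: np.ndarray | None = None) -> None:
    """Plain text allele-count matrix: rows = individuals, columns = loci."""
    dos = pop.dosage(loci)
    df = pd.DataFrame(dos, index=pd.Index(pop.ids, name="id"))
    df.to_csv(path, sep="\t")


def write_architecture(path: str | Path, arch: TraitArchitecture,
                       gmap: GeneticMap) -> None:
    df = pd.DataFrame({
        "qtl_index": gmap.qtl_idx,
        "position_morgan": gmap.qtl_positions(),
        "a": arch.a,
        "d": arch.d,
        "h": arch.h,
    })
    with open(path, "w") as fh:
        fh.write(f"# scale_a={arch.scale_a!r}\tscale_d={arch.scale_d!r}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_architecture(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_estimates(path: str | Path, est: MarkerEstimates,
                    gmap: GeneticMap) -> None:
    pd.DataFrame({
        "snp_index": gmap.snp_idx,
        "position_morgan": gmap.snp_positions(),
        "a_hat": est.a_hat,
        "d_hat": est.d_hat,
    }).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Delimited phenotype table with columns ``id`` and ``phenotype``."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"id", "phenotype"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
    return df


def write_manifest(path: str | Path, manifest: dict) -> None:
    """Persist a replicate/study manifest (seeds, config snapshot) as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
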
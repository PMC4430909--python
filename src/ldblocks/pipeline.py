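"""End-to-end pipeline: cluster -> select blocks -> Group Lasso.

The method runs chromosome by chromosome (the LD similarity is only
meaningful within a chromosome). Per chromosome: SNPs with undefined LD
are filtered, the constrained clustering is run on the LD kernel, the
number of blocks is chosen with the Gap statistic, missing genotypes are
imputed by the per-SNP mode (deliberately *after* the clustering, which
tolerates missing values), and the Group Lasso path is fitted on the
inferred blocks. All artifacts are plain TSV/JSON plus a run manifest
(parameters, seeds, versions) sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import BlockStructure, ClusterTree, cut, ward_constrained
from .gap import gap_profile
from .genotypes import GenotypeMatrix, impute_modal
from .ld import LDProvider, filter_undefined_ld
from .regression import RegressionProblem, group_lasso_path

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "write_blocks_bed",
    "write_merge_tree",
    "write_ld_pairs",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (mirrors the CLI flags)."""

    out_dir: str
    seed: int
    B: int = 100
    G_max: int | None = None
    workers: int = 1
    estimator: str = "em"
    log_gap: bool = False
    n_lambdas: int = 100
    chromosomes: list | None = None  # None = all
    covariates: str | None = None  # TSV path, samples x covariates


def write_blocks_bed(X: GenotypeMatrix, blocks: BlockStructure, path) -> None:
    """BED-like TSV: chrom, start_pos, end_pos (1-based inclusive),
    block_id, n_snps; positions from the first/last SNP of each block."""
    rows = []
    for g, (a, b) in enumerate(blocks.ranges):
        rows.append(
            (X.chrom[a], int(X.pos[a]), int(X.pos[b - 1]), f"block{g + 1}", b - a)
        )
    pd.DataFrame(
        rows, columns=["chrom", "start_pos", "end_pos", "block_id", "n_snps"]
    ).to_csv(path, sep="\t", index=False)


def write_merge_tree(tree: ClusterTree, path) -> None:
    rows = [
        (m.step_index, m.left[0], m.left[1], m.right[1], m.height)
        for m in tree.merges
    ]
    pd.DataFrame(
        rows, columns=["step", "left_start", "left_end", "right_end", "height"]
    ).to_csv(path, sep="\t", index=False)


def write_ld_pairs(provider: LDProvider, path) -> None:
    """Dump the LD pairs the provider actually computed."""
    rows = [
        (provider.X.snp_ids[j], provider.X.snp_ids[k], v)
        for (j, k), v in sorted(provider._cache.items())
    ]
    pd.DataFrame(rows, columns=["snp_i", "snp_j", "r2"]).to_csv(
        path, sep="\t", index=False
    )


def _load_covariates(path, sample_ids):
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.loc[sample_ids]
    return df.to_numpy(dtype=float)


def run_pipeline(X: GenotypeMatrix, y, config: PipelineConfig) -> dict:
    """Run the three-step method; writes artifacts and returns a summary.

    Returns a dict with, per chromosome: the inferred BlockStructure, the
    Gap profile, and the fitted Group Lasso path (on the imputed,
    chromosome-concatenated design).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    y = np.asarray(y, dtype=float)
    if len(y) != X.n:
        raise ValueError("phenotype length does not match sample count")
    chroms = config.chromosomes or X.chromosomes()
    results = {}
    kept_parts = []
    block_sizes_all = []
    t0 = time.time()
    for ci, chrom in enumerate(chroms):
        Xc = X.subset_chromosome(chrom)
        Xc, dropped = filter_undefined_ld(Xc)
        if Xc.p < 2:
            logger.warning("chromosome %s has <2 usable SNPs; skipped", chrom)
            continue
        logger.info(
            "chromosome %s: %d SNPs (%d filtered as undefined-LD)",
            chrom, Xc.p, len(dropped),
        )
        tree = ward_constrained(LDProvider(Xc, estimator=config.estimator), Xc.p)
        prof = gap_profile(
            Xc, tree_obs=tree, B=config.B, G_max=config.G_max,
            seed=[config.seed, ci],  # per-chromosome deterministic substream
            workers=config.workers, estimator=config.estimator,
            log_gap=config.log_gap,
        )
        blocks = cut(tree, prof.G_hat)
        write_blocks_bed(Xc, blocks, out / f"blocks_chr{chrom}.bed")
        write_merge_tree(tree, out / f"merges_chr{chrom}.tsv")
        prof.to_frame().to_csv(out / f"gap_profile_chr{chrom}.tsv", sep="\t", index=False)
        Xc_imp = impute_modal(Xc)
        kept_parts.append(Xc_imp)
        block_sizes_all.extend(blocks.sizes.tolist())
        results[str(chrom)] = {"blocks": blocks, "gap": prof, "tree": tree}

    if not kept_parts:
        raise ValueError("no chromosome produced a usable block structure")
    design = np.hstack([part.values.astype(float) for part in kept_parts])
    snp_ids = np.concatenate([part.snp_ids for part in kept_parts])
    groups = BlockStructure.from_sizes(block_sizes_all)
    covs = (
        _load_covariates(config.covariates, X.sample_ids)
        if config.covariates
        else None
    )
    problem = RegressionProblem.from_data(design, y, groups=groups, covariates=covs)
    path = group_lasso_path(problem, n_lambdas=config.n_lambdas)
    path.to_frame(snp_ids).to_csv(out / "group_lasso_path.tsv", sep="\t", index=False)
    results["path"] = path
    results["groups"] = groups

    manifest = {
        "package": "ldblocks",
        "version": __version__,
        "config": asdict(config),
        "n_samples": int(X.n),
        "n_snps": int(X.p),
        "chromosomes": [str(c) for c in chroms],
        "G_hat": {str(c): int(results[str(c)]["gap"].G_hat) for c in results
                  if c not in ("path", "groups")},
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
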
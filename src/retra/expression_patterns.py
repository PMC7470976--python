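"""Expression-presence rules, tissue specificity, housekeeping sets, and
dominant-isoform switching.

A feature is expressed in a biological condition (tissue, stage) when
strictly more than ``fpkm_min`` FPKM is seen in at least ``min_samples`` of
the condition's samples; expressed in a tissue when expressed in >= 1 of its
conditions; housekeeping when expressed in every tissue of the panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .annotation_model import Annotation

log = logging.getLogger(__name__)

META_COLUMNS = ("sample_id", "tissue", "stage", "sex", "replicate")


@dataclass
class ExpressionMatrix:
    """FPKM values (features x samples) with per-sample metadata."""

    values: pd.DataFrame          # index: feature ids, columns: sample ids
    meta: pd.DataFrame            # index: sample ids, columns: tissue/stage/sex/replicate
    level: str = "transcript"     # "gene" or "transcript"

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("negative FPKM values")
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        dup = self.meta[["tissue", "stage", "sex", "replicate"]].duplicated()
        if dup.any():
            raise ValueError("duplicate (tissue, stage, sex, replicate) metadata")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.meta["tissue"].unique())


def read_expression(matrix_path, meta_path, level: str = "transcript") -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, meta, level)


def write_expression(m: ExpressionMatrix, matrix_path, meta_path) -> None:
    m.values.to_csv(matrix_path, sep="\t")
    m.meta.to_csv(meta_path, sep="\t")


def expressed_in_condition(
    m: ExpressionMatrix,
    fpkm_min: float = 0.5,
    min_samples: int = 2,
    by_sex: bool = False,
) -> pd.DataFrame:
    """Boolean feature x condition table; condition = (tissue, stage), sexes
    pooled unless ``by_sex``.  Strictly-greater threshold; conditions with
    fewer than min_samples total samples are flagged and evaluated on what
    is available."""
    keys = ["tissue", "stage"] + (["sex"] if by_sex else [])
    cols: dict[str, pd.Series] = {}
    for cond, sub in m.meta.groupby(keys, sort=True):
        samples = [s for s in sub.index if s in m.values.columns]
        if len(samples) < min_samples:
            log.warning("condition %s has only %d samples", cond, len(samples))
        name = "/".join(str(c) for c in (cond if isinstance(cond, tuple) else (cond,)))
        cols[name] = (m.values[samples] > fpkm_min).sum(axis=1) >= min_samples
    return pd.DataFrame(cols, index=m.values.index)


def expressed_in_tissue(condition_table: pd.DataFrame) -> pd.DataFrame:
    """OR over each tissue's conditions (tissue = first '/'-field)."""
    tissues = sorted({c.split("/")[0] for c in condition_table.columns})
    return pd.DataFrame(
        {
            t: condition_table[
                [c for c in condition_table.columns if c.split("/")[0] == t]
            ].any(axis=1)
            for t in tissues
        },
        index=condition_table.index,
    )


def specificity_partition(tissue_table: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue counts of uniquely expressed vs shared ('common') features."""
    n_tissues = tissue_table.sum(axis=1)
    rows = []
    for t in tissue_table.columns:
        expressed = tissue_table[t]
        unique = int((expressed & (n_tissues == 1)).sum())
        common = int((expressed & (n_tissues >= 2)).sum())
        rows.append({"tissue": t, "unique": unique, "common": common})
    return pd.DataFrame(rows).set_index("tissue")


def housekeeping(tissue_table: pd.DataFrame) -> set[str]:
    """Features expressed in every tissue of the panel."""
    if tissue_table.shape[1] < 2:
        raise ValueError("housekeeping needs >= 2 tissues")
    mask = tissue_table.all(axis=1)
    return set(tissue_table.index[mask])


@dataclass
class IsoformSwitch:
    gene_id: str
    dominant: dict[str, str]   # tissue -> dominant transcript id
    tied: bool                 # any tie broken lexicographically


def dominant_isoform_switches(
    m: ExpressionMatrix,
    a: Annotation,
    genes: set[str] | None = None,
    fpkm_min: float = 0.5,
    min_samples: int = 2,
) -> list[IsoformSwitch]:
    """Genes whose dominant isoform (highest mean FPKM over a tissue's
    samples; ties -> lexicographically smallest id, flagged) differs between
    at least two tissues where the gene is expressed."""
    if m.level != "transcript":
        raise ValueError("needs a transcript-level matrix")
    tx2gene = {t.transcript_id: t.gene_id for t in a.transcripts()}
    gene_tx: dict[str, list[str]] = {}
    for tid in m.values.index:
        gid = tx2gene.get(tid)
        if gid is not None and (genes is None or gid in genes):
            gene_tx.setdefault(gid, []).append(tid)

    cond = expressed_in_condition(m, fpkm_min=fpkm_min, min_samples=min_samples)
    tissue_tab = expressed_in_tissue(cond)
    tissue_samples = {
        t: [s for s in m.meta.index[m.meta["tissue"] == t] if s in m.values.columns]
        for t in m.tissues
    }

    switches: list[IsoformSwitch] = []
    for gid in sorted(gene_tx):
        tids = sorted(gene_tx[gid])
        if len(tids) < 2:
            continue
        dominant: dict[str, str] = {}
        tied = False
        for tissue, samples in sorted(tissue_samples.items()):
            if not tissue_tab.loc[tids, tissue].any():
                continue  # gene not expressed in this tissue
            means = m.values.loc[tids, samples].mean(axis=1)
            top = means.max()
            winners = sorted(means.index[means == top])
            if len(winners) > 1:
                tied = True
            dominant[tissue] = winners[0]
        if len(set(dominant.values())) >= 2:
            switches.append(IsoformSwitch(gid, dominant, tied))
    return switches
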
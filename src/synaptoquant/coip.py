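"""Label-free co-immunoprecipitation enrichment analysis.

Quantification chain for pull-down mass-spectrometry experiments comparing a
bait strain against a control across three independent experiments:

1. **TOP3 abundance** — protein abundance per (experiment, group) is the mean
   intensity of its three most intense peptides (mean of those present when a
   protein yields fewer than three).
2. **Presence filter** — keep proteins observed in at least one group in at
   least two distinct experiments.
3. **Imputation** — each missing abundance is set to the minimum observed
   abundance of its experiment (over all proteins and both groups; a
   per-group mode is available).
4. **Log2 ratios** — per experiment, log2(bait / control).
5. **Enrichment call** — a protein is enriched when its ratio reaches the
   fold threshold (2-fold, i.e. log2 ratio >= 1, boundary inclusive) in every
   experiment.
6. **Annotation** — flag enriched proteins that are known V-ATPase subunits,
   with the immunoprecipitation bait flagged separately.

The chain is order-enforced: filtering before imputation (imputation would
otherwise manufacture presence), imputation before ratios (ratios need
complete positive values).  A worked example — the 12-protein enriched set of
a V5-tagged CG31030 pull-down from fly head extracts, entering the chain at
the ratio stage — ships with the package (:func:`load_table3`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import PipelineOrderError, ValidationError

__all__ = [
    "AbundanceMatrix",
    "EnrichmentResult",
    "top3_abundance",
    "presence_filter",
    "impute_missing",
    "log2_ratios",
    "call_enriched",
    "annotate_vatpase",
    "run_chain",
    "load_table3",
    "load_vatpase_genes",
    "BAIT_GENE",
]

GROUPS = ("bait", "control")
BAIT_GENE = "CG31030"

_STAGES = ("raw", "filtered", "imputed")


@dataclass
class AbundanceMatrix:
    """Protein x (experiment, group) abundances with explicit pipeline stage.

    ``data`` is indexed by protein identifier with a two-level column index
    (experiment, group); missing cells are NaN.  ``meta`` carries per-protein
    annotation (gene_symbol, accession).  ``stage`` records progress through
    the enforced chain raw -> filtered -> imputed.
    """

    data: pd.DataFrame
    meta: pd.DataFrame | None = None
    stage: str = "raw"
    peptide_counts: pd.DataFrame | None = None
    dropped: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if not isinstance(self.data.columns, pd.MultiIndex) or self.data.columns.nlevels != 2:
            raise ValidationError("data columns must be a (experiment, group) MultiIndex")
        bad_groups = set(self.data.columns.get_level_values(1)) - set(GROUPS)
        if bad_groups:
            raise ValidationError(f"unknown groups {sorted(bad_groups)}; expected {GROUPS}")
        if len(self.experiments) < 1:
            raise ValidationError("at least one experiment is required")
        vals = self.data.to_numpy(dtype=float)
        observed = ~np.isnan(vals)
        if np.any(vals[observed] <= 0) or not np.all(np.isfinite(vals[observed])):
            raise ValidationError("observed abundances must be finite and > 0")
        if self.meta is None:
            self.meta = pd.DataFrame(
                {"gene_symbol": self.data.index, "accession": self.data.index},
                index=self.data.index,
            )

    @property
    def experiments(self) -> list:
        return sorted(set(self.data.columns.get_level_values(0)))

    def _require_stage(self, expected: str, op: str) -> None:
        if self.stage != expected:
            raise PipelineOrderError(
                f"{op} requires a matrix at stage {expected!r}, got {self.stage!r}; "
                "the chain is presence_filter -> impute_missing -> log2_ratios"
            )


def top3_abundance(peptides: pd.DataFrame) -> AbundanceMatrix:
    """TOP3 protein abundance from a peptide intensity table.

    ``peptides`` columns: protein_id, peptide_id, experiment, group, intensity
    (optionally gene_symbol, accession).  Rows with NaN intensity are treated
    as unobserved.  Abundance per (protein, experiment, group) is the mean of
    the three highest peptide intensities; with fewer than three peptides the
    mean of those present is used, and the peptide count is kept alongside so
    such cells remain identifiable.
    """
    required = {"protein_id", "peptide_id", "experiment", "group", "intensity"}
    missing = required - set(peptides.columns)
    if missing or peptides.empty:
        raise ValidationError(
            f"peptide table is empty or lacks columns {sorted(missing)}"
            if missing
            else "peptide table is empty"
        )
    obs = peptides.dropna(subset=["intensity"])
    grouped = obs.groupby(["protein_id", "experiment", "group"])["intensity"]
    top3 = grouped.apply(lambda s: s.nlargest(3).mean())
    counts = grouped.size()
    data = top3.unstack(["experiment", "group"]).sort_index(axis=1)
    pep_counts = counts.unstack(["experiment", "group"]).reindex(columns=data.columns)
    # Protein universe includes proteins whose every intensity was missing.
    all_proteins = pd.Index(peptides["protein_id"].unique(), name="protein_id")
    data = data.reindex(all_proteins)
    pep_counts = pep_counts.reindex(all_proteins)
    meta_cols = [c for c in ("gene_symbol", "accession") if c in peptides.columns]
    meta = (
        peptides.drop_duplicates("protein_id").set_index("protein_id")[meta_cols]
        if meta_cols
        else None
    )
    if meta is not None:
        meta = meta.reindex(all_proteins)
        if "gene_symbol" not in meta:
            meta["gene_symbol"] = meta.index
        if "accession" not in meta:
            meta["accession"] = meta.index
    return AbundanceMatrix(data=data, meta=meta, stage="raw", peptide_counts=pep_counts)


def presence_filter(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Keep proteins observed in >= 1 group in >= 2 distinct experiments.

    Dropped proteins are logged (with the number of experiments they appeared
    in) on the returned matrix's ``dropped`` attribute.
    """
    matrix._require_stage("raw", "presence_filter")
    present = matrix.data.notna()
    per_exp = present.T.groupby(level=0).any().T  # protein x experiment
    n_exp = per_exp.sum(axis=1)
    keep = n_exp >= 2
    dropped = pd.DataFrame(
        {
            "n_experiments_present": n_exp[~keep],
            "reason": "present in fewer than 2 experiments",
        }
    )
    return AbundanceMatrix(
        data=matrix.data.loc[keep].copy(),
        meta=matrix.meta.loc[keep].copy(),
        stage="filtered",
        peptide_counts=None
        if matrix.peptide_counts is None
        else matrix.peptide_counts.loc[keep].copy(),
        dropped=dropped,
    )


def impute_missing(matrix: AbundanceMatrix, per_group: bool = False) -> AbundanceMatrix:
    """Replace missing abundances by the minimum abundance of the experiment.

    The minimum is taken over all proteins and both groups of the experiment
    (vendor convention); ``per_group=True`` restricts it to the same group.
    Observed values are never changed.
    """
    matrix._require_stage("filtered", "impute_missing")
    data = matrix.data.copy()
    for exp in matrix.experiments:
        block = data.loc[:, exp]
        if block.notna().sum().sum() == 0:
            raise ValidationError(f"experiment {exp!r} has no observed values")
        if per_group:
            for grp in block.columns:
                col = block[grp]
                if col.notna().sum() == 0:
                    raise ValidationError(f"experiment {exp!r} group {grp!r} has no values")
                data.loc[col.isna(), (exp, grp)] = col.min()
        else:
            exp_min = float(np.nanmin(block.to_numpy()))
            for grp in block.columns:
                data.loc[block[grp].isna(), (exp, grp)] = exp_min
    return AbundanceMatrix(
        data=data,
        meta=matrix.meta.copy(),
        stage="imputed",
        peptide_counts=matrix.peptide_counts,
        dropped=matrix.dropped,
    )


@dataclass
class EnrichmentResult:
    """Per-protein log2 bait/control ratios and downstream calls.

    ``table`` columns: gene_symbol, accession, log2_R<e> per experiment, and
    (once computed) enriched / is_vatpase / is_bait.
    """

    table: pd.DataFrame
    experiments: list
    fold_threshold: float | None = None
    bait_gene: str | None = None

    @property
    def ratio_columns(self) -> list[str]:
        return [f"log2_R{e}" for e in self.experiments]

    @property
    def n_enriched(self) -> int:
        if "enriched" not in self.table:
            raise PipelineOrderError("call_enriched has not been applied")
        return int(self.table["enriched"].sum())

    @property
    def n_vatpase_nonbait(self) -> int:
        if "is_vatpase" not in self.table:
            raise PipelineOrderError("annotate_vatpase has not been applied")
        return int((self.table["is_vatpase"] & ~self.table["is_bait"]).sum())

    def summary(self) -> str:
        lines = [
            "Co-IP enrichment result",
            "=" * 41,
            f"{'proteins':<32}{len(self.table):>9d}",
            f"{'experiments':<32}{len(self.experiments):>9d}",
        ]
        if self.fold_threshold is not None:
            lines.append(f"{'fold threshold':<32}{self.fold_threshold:>9g}")
            lines.append(f"{'enriched proteins':<32}{self.n_enriched:>9d}")
        if "is_vatpase" in self.table:
            lines.append(f"{'V-ATPase subunits (non-bait)':<32}{self.n_vatpase_nonbait:>9d}")
            bait = self.table.loc[self.table["is_bait"], "gene_symbol"].tolist()
            lines.append(f"{'bait':<32}{', '.join(map(str, bait)) or '-':>9}")
        return "\n".join(lines)


def log2_ratios(matrix: AbundanceMatrix) -> EnrichmentResult:
    """Per-experiment log2(bait abundance / control abundance) per protein."""
    matrix._require_stage("imputed", "log2_ratios")
    out = pd.DataFrame(index=matrix.data.index)
    out["gene_symbol"] = matrix.meta["gene_symbol"]
    out["accession"] = matrix.meta.get("accession", matrix.meta.index)
    for exp in matrix.experiments:
        bait = matrix.data[(exp, "bait")].to_numpy(dtype=float)
        ctrl = matrix.data[(exp, "control")].to_numpy(dtype=float)
        if np.any(~np.isfinite(bait)) or np.any(~np.isfinite(ctrl)):
            raise ValidationError(f"experiment {exp!r} still has missing values after imputation")
        if np.any(bait <= 0) or np.any(ctrl <= 0):
            raise ValidationError("abundances must be positive to form log2 ratios")
        out[f"log2_R{exp}"] = np.log2(bait / ctrl)
    return EnrichmentResult(table=out, experiments=matrix.experiments)


def call_enriched(result: EnrichmentResult, fold_threshold: float = 2.0) -> EnrichmentResult:
    """Flag proteins with >= ``fold_threshold``-fold bait/control abundance in
    every experiment (boundary inclusive: log2 ratio >= log2(threshold))."""
    if fold_threshold <= 0:
        raise ValidationError("fold_threshold must be > 0")
    cut = math.log2(fold_threshold)
    ratios = result.table[result.ratio_columns]
    enriched = (ratios >= cut).all(axis=1) & ratios.notna().all(axis=1)
    table = result.table.copy()
    table["enriched"] = enriched
    return EnrichmentResult(
        table=table,
        experiments=result.experiments,
        fold_threshold=fold_threshold,
        bait_gene=result.bait_gene,
    )


def annotate_vatpase(
    result: EnrichmentResult,
    subunit_genes: list[str] | None = None,
    bait_gene: str = BAIT_GENE,
) -> EnrichmentResult:
    """Flag enriched proteins that are known V-ATPase subunits.

    The bait is flagged separately (``is_bait``) and excluded from the
    non-bait subunit count even if it appears in the gene list.
    """
    if "enriched" not in result.table:
        raise PipelineOrderError("annotate_vatpase requires call_enriched first")
    genes = set(load_vatpase_genes() if subunit_genes is None else subunit_genes)
    table = result.table.copy()
    table["is_bait"] = table["gene_symbol"] == bait_gene
    table["is_vatpase"] = (
        table["enriched"] & table["gene_symbol"].isin(genes) & ~table["is_bait"]
    )
    return EnrichmentResult(
        table=table,
        experiments=result.experiments,
        fold_threshold=result.fold_threshold,
        bait_gene=bait_gene,
    )


def run_chain(
    matrix: AbundanceMatrix,
    fold_threshold: float = 2.0,
    subunit_genes: list[str] | None = None,
    bait_gene: str = BAIT_GENE,
    per_group_imputation: bool = False,
) -> EnrichmentResult:
    """Full chain: presence filter -> imputation -> ratios -> call -> annotation."""
    filtered = presence_filter(matrix)
    imputed = impute_missing(filtered, per_group=per_group_imputation)
    result = log2_ratios(imputed)
    result = call_enriched(result, fold_threshold=fold_threshold)
    return annotate_vatpase(result, subunit_genes=subunit_genes, bait_gene=bait_gene)


# ---------------------------------------------------------------------------
# packaged worked example


def _data_path(name: str):
    return resources.files("synaptoquant.data").joinpath(name)


def load_table3() -> EnrichmentResult:
    """The packaged 12-protein worked example, entering at the ratio stage.

    The source table mixes '.' and ',' decimal separators; the loader
    normalises ',' to '.' before parsing.
    """
    with _data_path("table3_log2_ratios.csv").open("r", encoding="utf-8") as fh:
        raw = pd.read_csv(fh, dtype=str)
    table = pd.DataFrame(index=raw.index)
    table["gene_symbol"] = raw["gene_symbol"]
    table["accession"] = raw["flybase_id"]
    for i, col in enumerate(("log2_R1", "log2_R2", "log2_R3"), start=1):
        table[f"log2_R{i}"] = raw[col].str.replace(",", ".", regex=False).astype(float)
    table.index = pd.Index(raw["flybase_id"], name="protein_id")
    return EnrichmentResult(table=table, experiments=[1, 2, 3])


def load_vatpase_genes() -> list[str]:
    """Bundled list of Drosophila V-ATPase subunit / accessory gene symbols."""
    with _data_path("vatpase_genes.txt").open("r", encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
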
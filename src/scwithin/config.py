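"""Typed pipeline configuration (YAML) with strict validation.

Unknown keys are rejected everywhere (typo safety) and every threshold is
range-checked before any stage runs.  Defaults bake in the emulated
study's analysis parameters: marker-call threshold p0 = 0.01, FDR = 0.05,
network candidate cutoff nominal p = 0.001, hub degree >= 4, t-SNE
perplexity 20 with 3000 iterations.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["PipelineConfig", "validate_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticSection(_Strict):
    enabled: bool = True
    n_participants: int = Field(2, ge=2)
    n_cells_per_sample: int = Field(600, gt=0)
    n_genes: int = Field(1500, gt=0)
    n_shared_degs: int = Field(10, ge=0)
    n_specific_degs_per_type: int = Field(3, ge=0)
    shared_lfc: float = Field(0.8, gt=0)
    specific_lfc: float = Field(1.0, gt=0)
    marker_fold: float = Field(4.0, gt=1)
    program_genes_per_type: int = Field(50, ge=0)
    program_fold: float = Field(3.0, gt=1)
    participant_effect_sd: float = Field(0.5, ge=0)
    planted_high_mito_cells: int = Field(0, ge=0)
    planted_doublet_cells: int = Field(0, ge=0)


class InputSection(_Strict):
    matrix_dir: Path | None = None
    sample_sheet: Path | None = None
    marker_panel: Path | None = None
    edge_list: Path | None = None
    gene_sets: Path | None = None


class QCSection(_Strict):
    min_genes_per_cell: int = Field(370, gt=0)
    max_mito_fraction: float = Field(0.10, gt=0, le=1)
    max_reads_per_cell: int = Field(100_000, gt=0)
    min_cells_per_gene_with_umi: int = Field(1, gt=0)
    batch_key: str = "participant"
    combat_covariates: tuple[str, ...] = ("condition",)


class ClusterSection(_Strict):
    n_pcs: int = Field(30, gt=0)
    perplexity: float = Field(20.0, gt=0)
    n_iter: int = Field(3000, gt=0)
    knn_k: int = Field(60, gt=0)


class MappingSection(_Strict):
    p0: float = Field(0.01, gt=0, le=1)
    min_cluster_frac: float = Field(0.005, gt=0, lt=1)


class DESection(_Strict):
    fdr: float = Field(0.05, gt=0, le=1)
    min_cells: int = Field(50, gt=0)
    min_frac: float = Field(0.01, gt=0, le=1)


class NetworkSection(_Strict):
    p_nom: float = Field(0.001, gt=0, le=1)
    hub_min_degree: int = Field(4, gt=0)
    fdr: float = Field(0.05, gt=0, le=1)
    min_stratum_cells: int = Field(10, gt=0)
    receptor: str | None = None
    receptor_cell_type: str | None = None
    min_set_size: int = Field(5, gt=0)


class PipelineConfig(_Strict):
    seed: int = 0
    outdir: Path = Path("scwithin_run")
    synthetic: SyntheticSection | None = None
    inputs: InputSection = InputSection()
    qc: QCSection = QCSection()
    cluster: ClusterSection = ClusterSection()
    mapping: MappingSection = MappingSection()
    de: DESection = DESection()
    network: NetworkSection = NetworkSection()

    @model_validator(mode="after")
    def _check_mode(self) -> "PipelineConfig":
        synthetic = self.synthetic is not None and self.synthetic.enabled
        if not synthetic:
            required = ("matrix_dir", "sample_sheet", "marker_panel")
            missing = [k for k in required if getattr(self.inputs, k) is None]
            if missing:
                raise ValueError(
                    f"real-data mode requires inputs: {missing} "
                    "(or set synthetic.enabled: true)"
                )
        return self


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML config file into a :class:`PipelineConfig`.

    Referenced input files must exist at validation time.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    config = PipelineConfig.model_validate(raw)
    if config.synthetic is None or not config.synthetic.enabled:
        for key in ("matrix_dir", "sample_sheet", "marker_panel",
                    "edge_list", "gene_sets"):
            p = getattr(config.inputs, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"inputs.{key}: {p} does not exist")
    return config
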
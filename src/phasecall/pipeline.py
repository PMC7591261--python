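"""End-to-end orchestration: filter -> normalize -> 5 adjacent-phase exact
tests -> phase-specific classification -> biotype summary, with deterministic
TSV outputs and a run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .difftest import DEGConfig, test_pair
from .errors import ValidationError
from .io import CountMatrix, write_table
from .norm import FilterConfig, NormalizationResult, compute_cpm, filter_expressed, normalize
from .phases import DEFAULT_DESIGN, PhaseDesign, classify_phase_specific, summarize_calls


@dataclass
class TMMOptions:
    m_trim: float = 0.30
    a_trim: float = 0.05
    reference: str = "auto"


@dataclass
class PipelineConfig:
    """All tunables of the calling pipeline in one place."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    deg: DEGConfig = field(default_factory=DEGConfig)
    tmm: TMMOptions = field(default_factory=TMMOptions)
    normalization: str = "tmm"  # "tmm" | "none"
    design: PhaseDesign = field(default_factory=PhaseDesign)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        known = {"filter", "deg", "tmm", "normalization", "design", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        if "filter" in raw:
            kwargs["filter"] = FilterConfig(**raw["filter"])
        if "deg" in raw:
            kwargs["deg"] = DEGConfig(**raw["deg"])
        if "tmm" in raw:
            kwargs["tmm"] = TMMOptions(**raw["tmm"])
        if "normalization" in raw:
            kwargs["normalization"] = raw["normalization"]
        if "design" in raw:
            kwargs["design"] = PhaseDesign(tuple(raw["design"]))
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design"] = list(self.design.phases)
        return d


@dataclass
class PipelineResult:
    filter_mask: pd.Series
    normalization: NormalizationResult
    pairwise: dict[tuple[str, str], pd.DataFrame]
    mean_cpm_by_phase: pd.DataFrame
    calls: pd.DataFrame
    summary: pd.DataFrame

    @property
    def assigned(self) -> pd.DataFrame:
        return self.calls[self.calls["assigned_phase"] != "none"]


def run_pipeline(
    cm: CountMatrix,
    biotypes: dict[str, str] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full phase-specific calling pipeline on a count matrix.

    The quantifiable-expression gate uses CPM on raw library sizes; TMM and
    all tests run on the retained genes.
    """
    config = config or PipelineConfig()
    cm.require_replicates(2)
    raw_cpm = compute_cpm(cm.counts, cm.library_size.to_numpy())
    mask = filter_expressed(raw_cpm, config.filter)
    filtered = cm.subset_genes(mask)
    norm = normalize(
        filtered,
        method=config.normalization,
        reference=config.tmm.reference,
        m_trim=config.tmm.m_trim,
        a_trim=config.tmm.a_trim,
    )
    pairwise = {
        (a, b): test_pair(filtered, a, b, norm, config.deg)
        for a, b in config.design.adjacent_pairs()
    }
    mean_cpm = pd.DataFrame(
        {
            q: norm.cpm[filtered.samples_in_phase(q)].mean(axis=1)
            for q in config.design.phases
        }
    )
    calls = classify_phase_specific(mean_cpm, pairwise, config.deg, config.design)
    summary = summarize_calls(calls, biotypes, config.design)
    return PipelineResult(
        filter_mask=pd.Series(mask, index=cm.gene_ids, name="kept"),
        normalization=norm,
        pairwise=pairwise,
        mean_cpm_by_phase=mean_cpm,
        calls=calls,
        summary=summary,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _pair_slug(a: str, b: str) -> str:
    clean = lambda s: s.replace("/", "")  # noqa: E731
    return f"{clean(a)}_vs_{clean(b)}"


def write_results(
    result: PipelineResult,
    out_dir,
    config: PipelineConfig,
    input_paths: dict[str, str] | None = None,
) -> None:
    """Write all stage outputs plus a manifest; reruns are byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(
        result.filter_mask.rename_axis("gene_id").reset_index(), out / "filter_mask.tsv"
    )
    norm_table = pd.DataFrame(
        {
            "sample_id": result.normalization.tmm_factor.index,
            "tmm_factor": result.normalization.tmm_factor.to_numpy(),
            "effective_library_size": result.normalization.effective_library_size.to_numpy(),
        }
    )
    write_table(norm_table, out / "normalization.tsv", sort_by=None)
    for (a, b), table in result.pairwise.items():
        write_table(table.reset_index(drop=True), out / f"de_{_pair_slug(a, b)}.tsv")
    write_table(result.calls.reset_index(drop=True), out / "phase_calls.tsv")
    result.summary.reset_index().to_csv(out / "summary.tsv", sep="\t", index=False)
    manifest = {
        "package": "phasecall",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {
            name: _sha256(Path(p)) for name, p in (input_paths or {}).items()
        },
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
        "n_genes_input": int(len(result.filter_mask)),
        "n_genes_kept": int(result.filter_mask.sum()),
        "n_assigned": int(len(result.assigned)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
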
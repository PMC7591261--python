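"""Containers and readers/writers for counts, sample sheets, biotypes and gene sets.

The native interchange format is TSV throughout: a gene x sample count table
with a header row of sample ids, a sample sheet mapping samples to cell-cycle
phases and replicate indices, a two-column biotype table (or Ensembl-style GTF
gene lines), GMT gene-set collections and a survival table.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: The five cell-cycle phases of the synchronized design, in cycle order.
PHASES: tuple[str, ...] = ("G1", "G1/S", "S", "G2", "M")

#: Collapsed gene biotype categories.
BIOTYPES: tuple[str, ...] = ("protein_coding", "lncRNA", "pseudogene", "other")

#: Ensembl biotypes collapsed into the lncRNA category. Configurable via the
#: ``override`` argument of :func:`read_biotypes`.
LNCRNA_BIOTYPES: frozenset[str] = frozenset(
    {
        "lncRNA",
        "lincRNA",
        "antisense",
        "sense_intronic",
        "sense_overlapping",
        "processed_transcript",
        "bidirectional_promoter_lncRNA",
        "3prime_overlapping_ncRNA",
    }
)


def collapse_biotype(raw: str, override: dict[str, str] | None = None) -> str:
    """Map a raw (Ensembl) biotype string onto one of the four categories.

    Any biotype containing ``pseudogene`` collapses to ``pseudogene``; a fixed
    set of long-noncoding classes collapses to ``lncRNA``; ``protein_coding``
    maps to itself; everything else is ``other``. ``override`` entries win.
    """
    if override and raw in override:
        out = override[raw]
        if out not in BIOTYPES:
            raise ValidationError(
                f"override maps {raw!r} to {out!r}, not one of {BIOTYPES}"
            )
        return out
    if "pseudogene" in raw:
        return "pseudogene"
    if raw in LNCRNA_BIOTYPES:
        return "lncRNA"
    if raw == "protein_coding":
        return "protein_coding"
    return "other"


@dataclass
class CountMatrix:
    """Integer gene x sample counts with phase/replicate metadata.

    Parameters
    ----------
    counts
        Genes in rows (index = gene ids), samples in columns.
    samples
        One row per sample, columns ``sample_id``, ``phase``, ``replicate``;
        row order defines the sample order of ``counts``.
    library_size
        Per-sample sequencing depth. Defaults to the column sums of
        ``counts`` but may be supplied explicitly, e.g. when the matrix is a
        subset of a genome-wide library.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    library_size: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicated gene ids: {dups[:5]}")
        required = {"sample_id", "phase", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        bad_phase = set(self.samples["phase"]) - set(PHASES)
        if bad_phase:
            raise ValidationError(
                f"unknown phase labels {sorted(bad_phase)}; allowed: {list(PHASES)}"
            )
        if (self.samples["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate indices must be >= 1")
        sheet_ids = list(self.samples["sample_id"])
        if len(set(sheet_ids)) != len(sheet_ids):
            raise ValidationError("duplicated sample ids in sample sheet")
        mat_ids = list(self.counts.columns)
        if set(mat_ids) != set(sheet_ids):
            only_mat = sorted(set(mat_ids) - set(sheet_ids))
            only_sheet = sorted(set(sheet_ids) - set(mat_ids))
            raise ValidationError(
                "counts/sample-sheet mismatch: "
                f"only in counts {only_mat}, only in sheet {only_sheet}"
            )
        # sample order follows the sheet
        self.counts = self.counts[sheet_ids]
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            g, s = np.argwhere((arr < 0) | (arr != np.floor(arr)))[0]
            raise ValidationError(
                f"non-integer or negative count {arr[g, s]!r} at gene "
                f"{self.counts.index[g]!r}, sample {self.counts.columns[s]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0)
        else:
            self.library_size = pd.Series(self.library_size).reindex(sheet_ids)
            if self.library_size.isna().any():
                raise ValidationError("library_size missing for some samples")
        if (self.library_size <= 0).any():
            bad = self.library_size.index[self.library_size <= 0].tolist()
            raise ValidationError(f"non-positive library size for samples {bad}")
        self.library_size = self.library_size.astype(np.int64)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def phases_present(self) -> list[str]:
        present = set(self.samples["phase"])
        return [p for p in PHASES if p in present]

    def phase_of(self) -> pd.Series:
        """Phase label per sample id, in matrix column order."""
        return self.samples.set_index("sample_id")["phase"].reindex(self.sample_ids)

    def samples_in_phase(self, phase: str) -> list[str]:
        if phase not in PHASES:
            raise ValidationError(f"unknown phase {phase!r}")
        mask = self.samples["phase"] == phase
        return list(self.samples.loc[mask, "sample_id"])

    def subset_genes(self, keep) -> "CountMatrix":
        """Row-subset by boolean mask or gene-id list; metadata is shared."""
        sub = self.counts.loc[keep]
        return CountMatrix(sub, self.samples.copy(), self.library_size.copy())

    def require_replicates(self, min_per_phase: int = 2) -> None:
        counts = self.samples["phase"].value_counts()
        thin = [p for p in self.phases_present if counts.get(p, 0) < min_per_phase]
        if thin:
            raise ValidationError(
                f"phases {thin} have < {min_per_phase} samples; "
                "differential testing needs replicates"
            )


@dataclass
class GeneSet:
    set_id: str
    name: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared background universe."""

    sets: list[GeneSet] = field(default_factory=list)

    def restricted_to(self, universe: set[str], min_size: int = 0) -> "GeneSetCollection":
        out = []
        for gs in self.sets:
            members = tuple(m for m in gs.members if m in universe)
            if len(members) >= min_size:
                out.append(GeneSet(gs.set_id, gs.name, members))
        return GeneSetCollection(out)


def read_counts(path_counts, path_samples) -> CountMatrix:
    """Read a counts TSV (gene ids x sample ids) and a sample sheet TSV."""
    counts = pd.read_csv(path_counts, sep="\t", index_col=0)
    samples = pd.read_csv(path_samples, sep="\t", dtype={"sample_id": str, "phase": str})
    return CountMatrix(counts, samples)


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_biotypes(
    path,
    override: dict[str, str] | None = None,
    strip_versions: bool = False,
) -> dict[str, str]:
    """Read gene biotypes from a two-column TSV or from GTF gene lines.

    Returns a gene_id -> collapsed-category mapping. Genes absent from the
    file are treated as ``other`` downstream. Gene ids are opaque strings;
    with ``strip_versions`` a trailing Ensembl version suffix (``.7``) is
    removed, a common source of annotation/count-matrix mismatches.
    """
    path = str(path)
    if path.endswith((".gtf", ".gff")):
        mapping = _read_biotypes_gtf(path, override)
        if strip_versions:
            mapping = {g.rsplit(".", 1)[0]: b for g, b in mapping.items()}
        return mapping
    table = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if table.shape[1] < 2:
        raise ValidationError(f"{path}: biotype TSV needs two columns (gene_id, biotype)")
    # tolerate a header row
    if str(table.iloc[0, 0]).lower() in {"gene_id", "gene"}:
        table = table.iloc[1:]
    key = (lambda g: str(g).rsplit(".", 1)[0]) if strip_versions else str
    return {
        key(g): collapse_biotype(str(b), override)
        for g, b in zip(table.iloc[:, 0], table.iloc[:, 1])
    }


def _read_biotypes_gtf(path: str, override: dict[str, str] | None) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValidationError(
                    f"{path}:{lineno}: GTF line has {len(fields)} fields, expected 9"
                )
            if fields[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValidationError(f"{path}:{lineno}: gene line without gene_id")
            raw = attrs.get("gene_biotype", attrs.get("gene_type", ""))
            out[gene_id] = collapse_biotype(raw, override)
    return out


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (set_id TAB description TAB member...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            set_id, name = fields[0], fields[1]
            members = tuple(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                warnings.warn(f"{path}:{lineno}: dropping empty set {set_id!r}")
                continue
            sets.append(GeneSet(set_id, name, members))
    return GeneSetCollection(sets)


def read_survival(path) -> pd.DataFrame:
    """Read a survival TSV with columns sample_id, time, event, expression."""
    table = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event", "expression"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"survival table missing columns: {sorted(missing)}")
    if (table["time"] <= 0).any() or not np.isfinite(table["time"]).all():
        raise ValidationError("survival times must be finite and > 0")
    if not set(table["event"].astype(int)) <= {0, 1}:
        raise ValidationError("event must be 0 (censored) or 1 (event)")
    return table


FLOAT_FORMAT = "%.10g"


def write_table(table: pd.DataFrame, path, sort_by: str | None = "gene_id") -> None:
    """Write a result table as deterministic TSV.

    Rows are sorted by ``sort_by`` when that column exists; floats are
    rendered with fixed significant digits so reruns are byte-identical.
    """
    out = table.copy()
    if sort_by is not None and sort_by in out.columns:
        out = out.sort_values(sort_by, kind="mergesort")
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def write_counts(cm: CountMatrix, path_counts, path_samples) -> None:
    cm.counts.rename_axis("gene_id").to_csv(path_counts, sep="\t")
    cm.samples.to_csv(path_samples, sep="\t", index=False)
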
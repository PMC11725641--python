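"""Count tables, design sheets, gene annotations, and the nested design matrix.

File formats are plain delimited text: count tables are TSV with a
``locus_tag`` column followed by one integer column per sample (the shape
``bedtools map -o sum`` / ``-o count`` produces, with "." meaning
no overlap, parsed as 0); design sheets are TSV with the header
``sample_id strain stress level replicate batch``; annotations are BED or
GFF3 with 0-based half-open coordinates internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL_STRESS = "control"
CONTROL_LEVEL = "none"
LEVELS = ("low", "medium", "high")

DESIGN_COLUMNS = ["sample_id", "strain", "stress", "level", "replicate", "batch"]


class CountsIOError(ValueError):
    """Malformed count table, design sheet, or annotation."""


@dataclass
class SampleDesign:
    """Per-sample experimental factors.

    One row per sample: strain (genetic background g), stress (proteotoxic
    stress e or ``control``), level (``none``/``low``/``medium``/``high``),
    replicate (positive integer) and batch label.  Control samples have
    stress ``control`` and level ``none``; stressed samples have a level.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise CountsIOError(f"design sheet missing columns: {missing}")
        t = self.table.reset_index(drop=True).copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["replicate"] = t["replicate"].astype(int)
        t["batch"] = t["batch"].astype(str)
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise CountsIOError(f"duplicated sample id {dup!r}")
        if (t["replicate"] < 1).any():
            raise CountsIOError("replicate numbers must be positive")
        is_ctrl = t["stress"] == CONTROL_STRESS
        if (is_ctrl & (t["level"] != CONTROL_LEVEL)).any():
            bad = t.loc[is_ctrl & (t["level"] != CONTROL_LEVEL), "sample_id"].iloc[0]
            raise CountsIOError(
                f"control sample {bad!r} carries a stress level; "
                f"controls must have level {CONTROL_LEVEL!r}"
            )
        if (~is_ctrl & (t["level"] == CONTROL_LEVEL)).any():
            bad = t.loc[~is_ctrl & (t["level"] == CONTROL_LEVEL), "sample_id"].iloc[0]
            raise CountsIOError(f"stressed sample {bad!r} has level {CONTROL_LEVEL!r}")
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def strains(self) -> list[str]:
        return sorted(self.table["strain"].unique())

    @property
    def batches(self) -> list[str]:
        return sorted(self.table["batch"].unique())

    def stresses(self, strain: str | None = None) -> list[str]:
        t = self.table if strain is None else self.table[self.table["strain"] == strain]
        return sorted(s for s in t["stress"].unique() if s != CONTROL_STRESS)

    def subset(self, mask: pd.Series | np.ndarray) -> "SampleDesign":
        return SampleDesign(self.table[np.asarray(mask)].reset_index(drop=True))

    def require_controls(self) -> None:
        """Every strain needs at least one control sample."""
        for g in self.strains:
            sub = self.table[self.table["strain"] == g]
            if not (sub["stress"] == CONTROL_STRESS).any():
                raise CountsIOError(f"strain {g!r} has no control samples")

    @classmethod
    def read(cls, path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t", dtype=str, comment="#").assign(
            replicate=lambda d: d["replicate"].astype(int)))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer matrix for one count channel.

    ``channel`` is ``"total"`` (summed reads over insertion sites per gene)
    or ``"unique"`` (number of distinct insertion sites per gene).
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    channel: str = "unique"

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        v = np.asarray(self.values)
        if v.shape != (len(self.genes), len(self.samples)):
            raise CountsIOError(
                f"count matrix shape {v.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.issubdtype(v.dtype, np.integer):
            if not np.allclose(v, np.round(v)):
                raise CountsIOError("count matrix has non-integer values")
            v = np.round(v).astype(np.int64)
        if (v < 0).any():
            raise CountsIOError("count matrix has negative entries")
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            for g in self.genes:
                if g in seen:
                    raise CountsIOError(f"duplicated locus tag {g!r}")
                seen.add(g)
        if self.channel not in ("total", "unique"):
            raise CountsIOError(f"unknown channel {self.channel!r}")
        self.values = v.astype(np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.genes, name="locus_tag"),
                            columns=self.samples)

    def reorder_samples(self, sample_ids: list[str]) -> "CountMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return CountMatrix(self.genes, list(sample_ids), self.values[:, idx],
                           self.channel)

    def subset_genes(self, genes: list[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.genes)}
        idx = [pos[g] for g in genes]
        return CountMatrix(list(genes), self.samples, self.values[idx, :], self.channel)

    def with_values(self, values: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.genes, self.samples, values, self.channel)


@dataclass
class GeneAnnotation:
    """Locus-tag coordinates, 0-based half-open (BED convention)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        req = ["locus_tag", "chromosome", "start", "end", "strand"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise CountsIOError(f"annotation missing columns: {missing}")
        t = self.table.reset_index(drop=True).copy()
        t["start"] = t["start"].astype(int)
        t["end"] = t["end"].astype(int)
        if (t["start"] >= t["end"]).any():
            bad = t.loc[t["start"] >= t["end"], "locus_tag"].iloc[0]
            raise CountsIOError(f"annotation interval for {bad!r} has start >= end")
        if t["locus_tag"].duplicated().any():
            dup = t.loc[t["locus_tag"].duplicated(), "locus_tag"].iloc[0]
            raise CountsIOError(f"duplicated locus tag {dup!r} in annotation")
        self.table = t

    @property
    def locus_tags(self) -> list[str]:
        return self.table["locus_tag"].tolist()


def read_count_table(path, channel: str) -> CountMatrix:
    """Read a TSV count table (``locus_tag`` + one numeric column per sample).

    bedtools' no-overlap sentinel "." and empty cells parse as 0.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.columns[0] != "locus_tag":
        df = df.rename(columns={df.columns[0]: "locus_tag"})
    genes = df["locus_tag"].astype(str).tolist()
    seen: set[str] = set()
    for g in genes:
        if g in seen:
            raise CountsIOError(f"duplicated locus tag {g!r} in {path}")
        seen.add(g)
    samples = [c for c in df.columns if c != "locus_tag"]
    raw = df[samples].replace(".", "0").fillna("0")
    values = np.empty((len(genes), len(samples)), dtype=np.int64)
    for jcol, s in enumerate(samples):
        for irow, cell in enumerate(raw[s]):
            cell = str(cell).strip() or "0"
            try:
                x = float(cell)
            except ValueError:
                raise CountsIOError(
                    f"non-numeric cell {cell!r} at gene {genes[irow]!r}, "
                    f"sample {s!r}") from None
            if x != int(x):
                raise CountsIOError(
                    f"non-integer cell {cell!r} at gene {genes[irow]!r}, sample {s!r}")
            values[irow, jcol] = int(x)
    return CountMatrix(genes, samples, values, channel)


def write_count_table(counts: CountMatrix, path) -> None:
    counts.to_frame().to_csv(path, sep="\t")


def read_annotation(path) -> GeneAnnotation:
    """Read BED (>=4 columns, name = locus tag) or GFF3 (locus_tag attribute)."""
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] not in ("gene", "CDS"):
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                tag = attrs.get("locus_tag") or attrs.get("ID")
                if tag is None:
                    continue
                # GFF is 1-based inclusive; convert to 0-based half-open
                rows.append({"locus_tag": tag, "chromosome": f[0],
                             "start": int(f[3]) - 1, "end": int(f[4]),
                             "strand": f[6]})
        return GeneAnnotation(pd.DataFrame(rows))
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    cols = {0: "chromosome", 1: "start", 2: "end", 3: "locus_tag"}
    df = df.rename(columns=cols)
    df["strand"] = df[5] if ncol > 5 else "+"
    return GeneAnnotation(df[["locus_tag", "chromosome", "start", "end", "strand"]])


def _level_key(x: str) -> int:
    return LEVELS.index(x) if x in LEVELS else 99


def build_design_matrix(design: SampleDesign, coding: str = "full") -> pd.DataFrame:
    """Encode the nested genotype -> stress -> level design as 0/1 columns.

    Columns come in three blocks, in deterministic order: strain indicators
    ``g[<strain>]``, stress-within-strain indicators ``e|g[<strain>:<stress>]``
    (1 for every level of that stress) and level-within-stress indicators
    ``s|e|g[<strain>:<stress>:<level>]``.  No intercept column is
    materialized; the fitter supplies it.

    ``coding="full"`` emits one column per strain, per (strain, stress) and
    per (strain, stress, level) — the overparameterized indicator coding the
    penalized GLM consumes (redundancy is resolved by the L1 penalty, and
    the unpenalized refit drops aliased columns).  ``coding="reference"``
    drops the first strain and the first level of each stress, yielding a
    linearly independent matrix on any complete design grid.
    """
    if coding not in ("full", "reference"):
        raise CountsIOError(f"unknown design coding {coding!r}")
    design.require_controls()
    t = design.table
    strains = design.strains
    g_block: dict[str, np.ndarray] = {}
    e_block: dict[str, np.ndarray] = {}
    s_block: dict[str, np.ndarray] = {}
    for g in (strains if coding == "full" else strains[1:]):
        g_block[f"g[{g}]"] = (t["strain"] == g).to_numpy(dtype=float)
    for g in strains:
        for e in design.stresses(g):
            m = (t["strain"] == g) & (t["stress"] == e)
            e_block[f"e|g[{g}:{e}]"] = m.to_numpy(dtype=float)
            present = sorted(t.loc[m, "level"].unique(), key=_level_key)
            levels = present if coding == "full" else present[1:]
            for s in levels:
                s_block[f"s|e|g[{g}:{e}:{s}]"] = (
                    m & (t["level"] == s)).to_numpy(dtype=float)
    X = pd.DataFrame({**g_block, **e_block, **s_block}, index=t["sample_id"])
    return X


def validate_dataset(counts_total: CountMatrix, counts_unique: CountMatrix,
                     design: SampleDesign) -> list[dict]:
    """Cross-check the two count channels against the design sheet.

    Returns a machine-readable list of issues (possibly empty); raises only
    on structural impossibility (mismatched gene lists).
    """
    issues: list[dict] = []
    if counts_total.genes != counts_unique.genes:
        raise CountsIOError("total and unique channels have different gene lists")
    if set(counts_total.samples) != set(counts_unique.samples):
        issues.append({"kind": "sample_mismatch",
                       "detail": "sample sets differ between channels"})
        return issues
    cu = counts_unique.reorder_samples(counts_total.samples)
    bad = np.argwhere(cu.values > counts_total.values)
    for i, j in bad[:100]:
        issues.append({"kind": "unique_gt_total",
                       "gene": counts_total.genes[i],
                       "sample": counts_total.samples[j],
                       "unique": int(cu.values[i, j]),
                       "total": int(counts_total.values[i, j])})
    design_samples = set(design.sample_ids)
    for s in counts_total.samples:
        if s not in design_samples:
            issues.append({"kind": "missing_design_row", "sample": s})
    for s in design_samples - set(counts_total.samples):
        issues.append({"kind": "missing_counts_column", "sample": s})
    for col in ("batch", "strain", "stress"):
        blank = design.table[col].astype(str).str.strip() == ""
        if blank.any():
            issues.append({"kind": f"missing {col}",
                           "sample": design.table.loc[blank, "sample_id"].iloc[0]})
    try:
        design.require_controls()
    except CountsIOError as exc:
        issues.append({"kind": "missing_control", "detail": str(exc)})
    return issues


def drop_all_zero_genes(counts_total: CountMatrix, counts_unique: CountMatrix
                        ) -> tuple[CountMatrix, CountMatrix, list[str]]:
    """Drop genes with zero counts in every sample of both channels."""
    cu = counts_unique.reorder_samples(counts_total.samples)
    keep = (counts_total.values.sum(axis=1) + cu.values.sum(axis=1)) > 0
    kept = [g for g, k in zip(counts_total.genes, keep) if k]
    dropped = [g for g, k in zip(counts_total.genes, keep) if not k]
    return counts_total.subset_genes(kept), cu.subset_genes(kept), dropped
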
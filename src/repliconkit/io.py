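"""Readers and writers for the external formats used across the toolkit.

All coordinates are held internally as 0-based half-open intervals on the
forward strand.  GFF3 input (1-based, inclusive) is converted at the boundary;
nothing downstream ever sees a 1-based coordinate.  Depth tables follow the
``samtools depth -a`` layout (replicon, 1-based position, depth) and are
aggregated into fixed windows on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
import skbio

__all__ = [
    "CDSRecord",
    "Replicon",
    "DETable",
    "read_genome",
    "read_depth_table",
    "read_de_table",
    "write_de_table",
    "write_tsv",
    "read_tsv",
    "write_newick",
    "read_newick",
    "write_fasta",
]

DEPTH_COLUMNS = ["replicon_id", "window_start", "window_end", "depth"]
DE_COLUMNS = ["gene_id", "replicon_id", "log2fc", "pvalue"]


@dataclass
class CDSRecord:
    """A protein-coding feature in internal coordinates (0-based, half-open)."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str = "+"
    phase: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"CDS {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in "+-":
            raise ValueError(f"CDS {self.gene_id}: strand must be '+' or '-'")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"CDS {self.gene_id}: phase must be 0, 1 or 2")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Replicon:
    """One replicon of a (multipartite) genome.

    ``declared_role`` records what the annotation claims the replicon is; the
    codon-usage classifier produces its own, independent call.
    """

    id: str
    length: int
    declared_role: str = "unknown"
    sequence: str | None = None
    cds_list: list[CDSRecord] = field(default_factory=list)

    ROLES = ("chromosome", "chromid", "plasmid", "unknown")

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"replicon {self.id}: length must be >= 1")
        if self.declared_role not in self.ROLES:
            raise ValueError(f"replicon {self.id}: unknown role {self.declared_role!r}")
        for cds in self.cds_list:
            self._check_bounds(cds)

    def _check_bounds(self, cds: CDSRecord) -> None:
        if cds.start < 0 or cds.end > self.length:
            raise ValueError(
                f"CDS {cds.gene_id} interval [{cds.start},{cds.end}) lies outside "
                f"replicon {self.id} of length {self.length}"
            )

    def cds_sequence(self, cds: CDSRecord) -> str:
        """Extract the coding-strand sequence of a CDS (reverse-complemented
        for minus-strand features), with the phase offset already trimmed."""
        if self.sequence is None:
            raise ValueError(f"replicon {self.id} carries no sequence")
        self._check_bounds(cds)
        raw = self.sequence[cds.start : cds.end]
        if cds.strand == "-":
            raw = str(Seq(raw).reverse_complement())
        return raw[cds.phase :]


@dataclass
class DETable:
    """Per-gene differential-expression results for one strain contrast."""

    strain: str
    reference: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DE_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"DE table missing required columns: {missing}")
        if self.data["gene_id"].duplicated().any():
            dups = self.data["gene_id"][self.data["gene_id"].duplicated()].tolist()
            raise ValueError(f"DE table has duplicated gene ids: {dups[:5]}")
        bad = self.data[(self.data["pvalue"] < 0) | (self.data["pvalue"] > 1)]
        if len(bad):
            raise ValueError(
                f"DE table p-values outside [0,1] for genes {bad['gene_id'].tolist()[:5]}"
            )


# ---------------------------------------------------------------------------
# genome reading


def _cds_from_gff3(path: str | Path) -> list[CDSRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    records = []
    for feat in db.features_of_type("CDS"):
        attrs = feat.attributes
        gene_id = (attrs.get("ID") or attrs.get("locus_tag") or attrs.get("Name") or [feat.id])[0]
        phase = 0 if feat.frame in (".", None) else int(feat.frame)
        records.append(
            CDSRecord(
                gene_id=gene_id,
                replicon_id=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand,
                phase=phase,
            )
        )
    return records


def _cds_from_tsv(path: str | Path) -> list[CDSRecord]:
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "replicon_id", "start", "end", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"CDS table {path} missing required columns: {missing}")
    if "phase" not in df.columns:
        df = df.assign(phase=0)
    return [
        CDSRecord(
            gene_id=str(r.gene_id),
            replicon_id=str(r.replicon_id),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            phase=int(r.phase),
        )
        for r in df.itertuples()
    ]


def read_genome(fasta_path: str | Path, annotation_path: str | Path) -> list[Replicon]:
    """Read replicon sequences plus CDS annotations.

    The annotation may be GFF3 (recognized by a .gff/.gff3 suffix; 1-based
    inclusive coordinates converted here) or a tab-separated CDS table that is
    already in internal 0-based half-open coordinates.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ValueError(f"no sequences found in {fasta_path}")
    suffix = Path(annotation_path).suffix.lower()
    cds_records = (
        _cds_from_gff3(annotation_path) if suffix in (".gff", ".gff3") else _cds_from_tsv(annotation_path)
    )
    by_replicon: dict[str, list[CDSRecord]] = {rid: [] for rid in seqs}
    for cds in cds_records:
        if cds.replicon_id not in seqs:
            raise ValueError(
                f"annotation references replicon {cds.replicon_id!r} absent from FASTA"
            )
        by_replicon[cds.replicon_id].append(cds)
    return [
        Replicon(id=rid, length=len(seq), sequence=seq, cds_list=by_replicon[rid])
        for rid, seq in seqs.items()
    ]


# ---------------------------------------------------------------------------
# depth tables


def read_depth_table(tsv_path: str | Path, window_bp: int = 1000) -> pd.DataFrame:
    """Read a depth table, windowing per-base input to ``window_bp`` windows.

    Two layouts are accepted:

    * per-base, three columns ``replicon  pos(1-based)  depth`` as produced by
      ``samtools depth -a`` — aggregated here to mean depth per fixed window;
      a trailing partial window is kept when it spans at least half a window;
    * pre-windowed, four columns ``replicon  window_start  window_end  depth``
      (0-based half-open) — passed through unchanged.

    Returns a DataFrame with columns ``replicon_id, window_start, window_end,
    depth``.
    """
    try:
        df = pd.read_csv(tsv_path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        warnings.warn(f"depth file {tsv_path} is empty")
        return pd.DataFrame(columns=DEPTH_COLUMNS)
    if df.shape[1] == 4 or (df.shape[1] >= 4 and set(DEPTH_COLUMNS) <= set(df.iloc[0])):
        # pre-windowed; tolerate an optional header row
        if not pd.api.types.is_numeric_dtype(df.iloc[:, 1]):
            df = pd.read_csv(tsv_path, sep="\t", comment="#")
            df = df[DEPTH_COLUMNS]
        else:
            df.columns = DEPTH_COLUMNS
        out = df.astype(
            {"replicon_id": str, "window_start": int, "window_end": int, "depth": float}
        )
    elif df.shape[1] == 3:
        df.columns = ["replicon_id", "pos", "depth"]
        df = df.astype({"replicon_id": str, "pos": int, "depth": float})
        if (df["depth"] < 0).any():
            raise ValueError(f"negative depth values in {tsv_path}")
        out = _window_per_base(df, window_bp)
    else:
        raise ValueError(
            f"depth file {tsv_path} has {df.shape[1]} columns; expected 3 (per-base) or 4 (windowed)"
        )
    if (out["depth"] < 0).any():
        raise ValueError(f"negative depth values in {tsv_path}")
    return out.reset_index(drop=True)


def _window_per_base(df: pd.DataFrame, window_bp: int) -> pd.DataFrame:
    rows = []
    for rid, sub in df.groupby("replicon_id", sort=True):
        if not sub["pos"].is_monotonic_increasing:
            warnings.warn(f"positions for {rid} are unsorted; sorting")
            sub = sub.sort_values("pos")
        start0 = sub["pos"].to_numpy() - 1  # samtools depth is 1-based
        widx = start0 // window_bp
        grouped = sub.assign(_w=widx).groupby("_w")["depth"]
        counts = grouped.size()
        means = grouped.mean()
        last = widx.max()
        for w in means.index:
            if w == last and counts[w] < window_bp / 2:
                continue  # drop a trailing sliver shorter than half a window
            rows.append((rid, int(w) * window_bp, (int(w) + 1) * window_bp, float(means[w])))
    return pd.DataFrame(rows, columns=DEPTH_COLUMNS)


# ---------------------------------------------------------------------------
# DE tables and generic TSV / newick round-trips


def read_de_table(tsv_path: str | Path, strain: str = "", reference: str = "") -> DETable:
    df = pd.read_csv(tsv_path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"DE table {tsv_path} missing required columns: {missing}")
    df = df[DE_COLUMNS].astype(
        {"gene_id": str, "replicon_id": str, "log2fc": float, "pvalue": float}
    )
    return DETable(strain=strain, reference=reference, data=df)


def write_de_table(table: DETable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_newick(tree: "skbio.TreeNode | str", path: str | Path) -> None:
    if isinstance(tree, str):
        tree = skbio.TreeNode.read([tree])
    tree.write(str(path))


def read_newick(path: str | Path) -> "skbio.TreeNode":
    return skbio.TreeNode.read(str(path))


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA, 70 columns per line."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
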
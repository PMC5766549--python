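"""Gene annotation, gene-set (GMT) and TF-catalog readers and writers.

Intervals are normalized internally to 1-based inclusive coordinates
regardless of the on-disk dialect: BED input is 0-based half-open, GFF3 is
1-based inclusive.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import FormatError

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end"]


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    df = df[ANNOTATION_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(int)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] < 1).any() or (df["end"] < df["start"]).any():
        raise FormatError("annotation has invalid 1-based inclusive intervals")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].head().tolist()
        raise FormatError(f"duplicate gene ids in annotation: {dupes}")
    return df.reset_index(drop=True)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into 1-based inclusive intervals."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "bed_start", "bed_end", "gene_id"],
    )
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"].astype(str),
            "chrom": df["chrom"],
            "start": df["bed_start"] + 1,
            "end": df["bed_end"],
        }
    )
    return _validate(out)


def write_bed(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write 1-based inclusive intervals as a BED file (0-based half-open)."""
    ann = _validate(annotation)
    out = pd.DataFrame(
        {
            "chrom": ann["chrom"],
            "start": ann["start"] - 1,
            "end": ann["end"],
            "gene_id": ann["gene_id"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gff3(path: str | Path, feature: str = "gene") -> pd.DataFrame:
    """Read gene intervals from a GFF3 file (already 1-based inclusive).

    The gene id is taken from the ``ID=`` attribute (``gene:`` prefix
    stripped), falling back to ``Name=``.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            raise FormatError(f"GFF3 line with {len(parts)} columns: {line[:60]}")
        if parts[2] != feature:
            continue
        attrs = dict(
            kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
        )
        gene_id = attrs.get("ID", attrs.get("Name"))
        if gene_id is None:
            raise FormatError(f"GFF3 {feature} record without ID/Name: {line[:60]}")
        gene_id = gene_id.removeprefix("gene:")
        rows.append((gene_id, parts[0], int(parts[3]), int(parts[4])))
    return _validate(pd.DataFrame(rows, columns=ANNOTATION_COLUMNS))


# ---------------------------------------------------------------------------
# GMT gene sets and TF catalogs
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets: ``name<TAB>description<TAB>gene...`` per line."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line with fewer than 3 fields: {line[:60]}")
        name, genes = parts[0], [g for g in parts[2:] if g]
        if name in sets:
            raise FormatError(f"duplicate gene-set name {name!r}")
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, name, *genes]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_tf_list(path: str | Path) -> set[str]:
    """Read a TF catalog: one gene symbol per line, ``#`` comments allowed."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_tf_list(tfs: set[str] | list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(tfs)) + "\n")
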
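"""Readers and writers for the pipeline's external formats.

Tabular inputs are UTF-8 TSV with a header row.  Count matrices are OTUs as
rows, samples as columns (the usual otutab layout); a transposed dialect is
auto-detected from the header sentinel.  Missing cells are errors, never
zeros, so contamination accounting stays explicit.  The indicator reference
list is YAML (or TSV with the same columns).
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    IndicatorEntry,
    IndicatorList,
    KicknetCommunity,
    ReadCountMatrix,
    SiteDetectionTable,
    TAXONOMY_RANKS,
    validate_taxonomy,
)
from .errors import FormatError, ValidationError

PathLike = Union[str, Path]

_OTU_SENTINELS = {"otu_id", "otu", "#otu id", "zotu"}
_SAMPLE_SENTINELS = {"sample_id", "sample"}


def _read_tsv(path: PathLike, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, **kw)
    except Exception as exc:  # pragma: no cover - pandas message wrapped
        raise FormatError(f"cannot parse TSV {path}: {exc}") from exc


def read_count_matrix(path: PathLike, meta_path: PathLike) -> ReadCountMatrix:
    """Read an OTU x sample count TSV plus its sample-metadata sidecar."""
    raw = _read_tsv(path)
    if raw.empty or raw.shape[1] < 2:
        raise FormatError(f"{path}: need an id column plus >= 1 data column")
    first = raw.columns[0].strip().lower()
    if first in _SAMPLE_SENTINELS:  # transposed dialect: samples as rows
        raw = raw.set_index(raw.columns[0]).T.reset_index(names="otu_id")
        first = "otu_id"
    if first not in _OTU_SENTINELS:
        raise FormatError(
            f"{path}: first header cell {raw.columns[0]!r} is not a "
            "recognized OTU or sample id sentinel"
        )
    counts = raw.set_index(raw.columns[0])
    counts.index.name = "otu_id"
    mat = np.empty(counts.shape, dtype=np.int64)
    for j, col in enumerate(counts.columns):
        for i, val in enumerate(counts[col]):
            if val is None or (isinstance(val, float) and np.isnan(val)):
                raise FormatError(
                    f"{path}: missing count for OTU {counts.index[i]!r} "
                    f"in sample {col!r} (missing cells are errors, not zeros)"
                )
            try:
                iv = int(val)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {val!r} for OTU "
                    f"{counts.index[i]!r} in sample {col!r}"
                )
            if iv < 0:
                raise FormatError(
                    f"{path}: negative count for OTU {counts.index[i]!r} "
                    f"in sample {col!r}"
                )
            mat[i, j] = iv
    counts = pd.DataFrame(mat, index=counts.index, columns=counts.columns)
    meta = read_sample_meta(meta_path)
    missing = set(counts.columns) - set(meta.index)
    if missing:
        raise ValidationError(
            f"{meta_path}: samples present in matrix but missing from "
            f"metadata: {sorted(missing)}"
        )
    return ReadCountMatrix(counts=counts, meta=meta.loc[list(counts.columns)])


def read_sample_meta(path: PathLike) -> pd.DataFrame:
    meta = _read_tsv(path)
    need = {"sample_id", "site_id", "replicate_index", "role"}
    if not need <= set(meta.columns):
        raise FormatError(
            f"{path}: sample metadata needs columns {sorted(need)}"
        )
    meta = meta.set_index("sample_id")
    meta["replicate_index"] = pd.to_numeric(
        meta["replicate_index"], errors="coerce"
    )
    meta["site_id"] = meta["site_id"].where(meta["site_id"].notna(), None)
    return meta


def write_count_matrix(matrix: ReadCountMatrix, path: PathLike,
                       meta_path: PathLike) -> None:
    counts = matrix.counts.copy()
    counts.index.name = "otu_id"
    counts.to_csv(path, sep="\t")
    meta = matrix.meta.copy()
    meta.index.name = "sample_id"
    out = meta.reset_index()[["sample_id", "site_id", "replicate_index", "role"]]
    out["replicate_index"] = out["replicate_index"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    out["site_id"] = out["site_id"].map(lambda v: "" if pd.isna(v) else v)
    out.to_csv(meta_path, sep="\t", index=False)


def read_taxonomy(path: PathLike) -> pd.DataFrame:
    """Read a per-OTU taxonomy TSV (ranks phylum..species, indicator link)."""
    tax = _read_tsv(path)
    if "otu_id" not in tax.columns:
        raise FormatError(f"{path}: taxonomy needs an otu_id column")
    tax = tax.set_index("otu_id")
    for rank in TAXONOMY_RANKS:
        if rank not in tax.columns:
            tax[rank] = None
    if "indicator_taxon" not in tax.columns:
        tax["indicator_taxon"] = None
    tax = tax.replace({np.nan: None, "": None})
    tax = tax[list(TAXONOMY_RANKS) + ["indicator_taxon"]]
    validate_taxonomy(tax, allow_rank_gaps=True)
    return tax


def write_taxonomy(tax: pd.DataFrame, path: PathLike) -> None:
    out = tax.copy()
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t", na_rep="")


def _entries_from_records(records) -> IndicatorList:
    entries = []
    for rec in records:
        gi = rec.get("gi_value")
        entries.append(
            IndicatorEntry(
                name=str(rec["name"]),
                rank=str(rec["rank"]),
                group=str(rec.get("group", rec["name"])),
                phylum=str(rec.get("phylum", "")),
                gi_value=None if gi in (None, "", "null") else int(gi),
                gi_min_abundance=int(rec.get("gi_min_abundance", 1)),
            )
        )
    return IndicatorList(entries=entries)


def read_indicator_list(path: PathLike) -> IndicatorList:
    """Read an indicator reference list from YAML or TSV."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if doc is None:
            return IndicatorList(entries=[])
        records = doc["entries"] if isinstance(doc, dict) else doc
    else:
        frame = _read_tsv(path)
        if frame.empty:
            return IndicatorList(entries=[])
        records = frame.replace({np.nan: None}).to_dict("records")
    return _entries_from_records(records or [])


def write_indicator_list(ind: IndicatorList, path: PathLike) -> None:
    records = [
        {
            "name": e.name,
            "rank": e.rank,
            "group": e.group,
            "phylum": e.phylum,
            "gi_value": e.gi_value,
            "gi_min_abundance": e.gi_min_abundance,
        }
        for e in ind
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"entries": records}, fh, sort_keys=False)


def default_indicator_list() -> IndicatorList:
    """The packaged 145-entry indicator-group reference."""
    ref = importlib.resources.files("ednaibch.data").joinpath(
        "ibch_indicator_groups.yaml"
    )
    with importlib.resources.as_file(ref) as path:
        return read_indicator_list(path)


def read_kicknet(path: PathLike,
                 indicators: Optional[IndicatorList] = None
                 ) -> list[KicknetCommunity]:
    """Read long-format kick-net counts (site_id, taxon, count)."""
    frame = _read_tsv(path)
    need = {"site_id", "taxon", "count"}
    if not need <= set(frame.columns):
        raise FormatError(f"{path}: kick-net table needs columns {sorted(need)}")
    if indicators is not None:
        known = set(indicators.names)
        bad = frame[~frame["taxon"].isin(known)]
        if not bad.empty:
            rows = [
                f"row {i + 2}: {t!r}"  # +2: header + 1-based
                for i, t in bad["taxon"].items()
            ]
            raise ValidationError(
                f"{path}: unknown indicator taxa ({'; '.join(rows[:10])})"
            )
    out = []
    for site, sub in frame.groupby("site_id", sort=True):
        counts = {}
        for _, row in sub.iterrows():
            try:
                counts[row["taxon"]] = int(row["count"])
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer count {row['count']!r} for "
                    f"site {site!r}, taxon {row['taxon']!r}"
                )
        out.append(KicknetCommunity(site_id=str(site), counts=counts))
    return out


def write_kicknet(communities: list[KicknetCommunity], path: PathLike) -> None:
    rows = [
        {"site_id": c.site_id, "taxon": t, "count": n}
        for c in communities
        for t, n in sorted(c.counts.items())
    ]
    pd.DataFrame(rows, columns=["site_id", "taxon", "count"]).to_csv(
        path, sep="\t", index=False
    )


def write_site_detection_table(table: SiteDetectionTable, path: PathLike) -> None:
    out = table.pooled_reads.copy()
    out.index.name = "site_id"
    out.to_csv(path, sep="\t")


def read_site_detection_table(path: PathLike) -> SiteDetectionTable:
    frame = _read_tsv(path)
    frame = frame.set_index(frame.columns[0])
    pooled = frame.astype(np.int64)
    return SiteDetectionTable(presence=pooled > 0, pooled_reads=pooled)
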
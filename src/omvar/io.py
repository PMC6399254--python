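"""Readers and writers for the text dialects the toolkit touches.

The BNX/CMAP/XMAP/SMAP dialects implemented here are minimal documented
subsets of the optical-mapping ecosystem's formats (see ``docs/formats.md``):
comment/header lines start with ``#``; unknown header lines are preserved as
opaque text on read and ignored otherwise. Internally every coordinate is
0-based half-open bp; these writers alone emit the ecosystem's 1-based
positions, and the readers convert back.
"""

from __future__ import annotations

import configparser
import logging
from pathlib import Path
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

from .models import Alignment, CohortMetadata, LabelMap, SVCall

logger = logging.getLogger("omvar")


def stage_log(stage: str, **counts) -> None:
    """One structured log line per pipeline stage (reproducibility audit)."""
    kv = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s %s", stage, kv)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# BNX subset (single-molecule maps)
#
#   # any number of header lines
#   0 <molecule_id> <length_bp>
#   1 <pos_1> <pos_2> ... <pos_k>          (1-based bp, label channel 1)
# ---------------------------------------------------------------------------

def _read_bnx(path: Path) -> List[LabelMap]:
    maps: List[LabelMap] = []
    cur_id = None
    cur_len = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "0":
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: malformed BNX molecule record")
                cur_id, cur_len = fields[1], float(fields[2])
            elif fields[0] == "1":
                if cur_id is None:
                    raise ParseError(f"{path}:{lineno}: label line before molecule line")
                pos = np.array([float(x) - 1.0 for x in fields[1:]], dtype=float)
                if pos.size and np.any(np.diff(pos) <= 0):
                    raise ParseError(f"{path}:{lineno}: non-monotone label positions")
                maps.append(LabelMap(cur_id, "molecule", cur_len, pos))
                cur_id = None
            else:
                raise ParseError(f"{path}:{lineno}: unknown BNX record type {fields[0]!r}")
    if cur_id is not None:
        # molecule declared with an empty label channel
        maps.append(LabelMap(cur_id, "molecule", cur_len, np.empty(0)))
    return maps


def _write_bnx(maps: Iterable[LabelMap], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# BNX subset 0.1\n#0h\tLabel\tMoleculeID\tLength\n")
        for m in maps:
            fh.write(f"0\t{m.map_id}\t{m.length_bp:.1f}\n")
            if m.n_labels:
                fh.write("1\t" + "\t".join(f"{p + 1.0:.1f}" for p in m.positions) + "\n")


# ---------------------------------------------------------------------------
# CMAP subset (reference / contig maps)
#
#   #h CMapId  ContigLength  NumSites  SiteID  LabelChannel  Position
# One row per label (channel 1); positions 1-based bp.
# ---------------------------------------------------------------------------

_CMAP_COLS = ["CMapId", "ContigLength", "NumSites", "SiteID", "LabelChannel", "Position"]


def _read_cmap(path: Path, kind: str = "reference") -> List[LabelMap]:
    rows = []
    lengths = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: malformed CMAP record")
            map_id, length, _nsites, _site, channel, pos = fields[:6]
            lengths[map_id] = float(length)
            if channel == "1":
                rows.append((map_id, float(pos) - 1.0, lineno))
    maps = []
    for map_id in dict.fromkeys(lengths):  # preserve file order
        pos = np.array([p for m, p, _ in rows if m == map_id], dtype=float)
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ParseError(f"{path}: map {map_id}: non-monotone positions")
        maps.append(LabelMap(map_id, kind, lengths[map_id], pos))
    return maps


def _write_cmap(maps: Iterable[LabelMap], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# CMAP subset 0.1\n#h\t" + "\t".join(_CMAP_COLS) + "\n")
        for m in maps:
            n = m.n_labels
            for i, p in enumerate(m.positions, 1):
                fh.write(f"{m.map_id}\t{m.length_bp:.1f}\t{n}\t{i}\t1\t{p + 1.0:.1f}\n")
            # channel-0 terminator row marks the map end (also encodes empty maps)
            fh.write(f"{m.map_id}\t{m.length_bp:.1f}\t{n}\t{n + 1}\t0\t{m.length_bp:.1f}\n")


def read_maps(path, dialect: str, kind: str | None = None) -> List[LabelMap]:
    """Read label maps from a BNX- or CMAP-subset file.

    Positions are converted to the internal 0-based convention.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "bnx":
        return _read_bnx(path)
    if dialect == "cmap":
        return _read_cmap(path, kind=kind or "reference")
    raise ValueError(f"unknown dialect {dialect!r}")


def write_maps(maps: Sequence[LabelMap], path, dialect: str) -> None:
    path = Path(path)
    if dialect == "bnx":
        _write_bnx(maps, path)
    elif dialect == "cmap":
        _write_cmap(maps, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# XMAP subset (alignments)
# ---------------------------------------------------------------------------

_XMAP_COLS = [
    "XmapEntryID", "QryContigID", "RefContigID", "RefStartPos", "RefEndPos",
    "Orientation", "Score", "Confidence", "Alignment",
]


def write_alignments(alignments: Sequence[Alignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("# XMAP subset 0.1\n#h\t" + "\t".join(_XMAP_COLS) + "\n")
        for i, a in enumerate(alignments, 1):
            pairs = "".join(f"({r + 1},{q + 1})" for q, r in a.pairs)
            fh.write(
                f"{i}\t{a.query_id}\t{a.ref_id}\t{a.ref_start_bp + 1.0:.1f}\t"
                f"{a.ref_end_bp:.1f}\t{a.orientation}\t{a.score:.4f}\t"
                f"{a.confidence:.4f}\t{pairs}\n"
            )


# ---------------------------------------------------------------------------
# SV calls: SMAP-like TSV (1-based start) and BED (0-based half-open)
# ---------------------------------------------------------------------------

_SMAP_COLS = [
    "chrom", "start", "end", "type", "size_delta", "zygosity", "support",
    "score", "module", "chrom2", "sample_id",
]


def write_sv_calls(calls: Sequence[SVCall], path, dialect: str = "smap_like") -> None:
    path = Path(path)
    if dialect == "smap_like":
        with open(path, "w") as fh:
            fh.write("# SMAP-like SV calls 0.1\n#h\t" + "\t".join(_SMAP_COLS) + "\n")
            for c in calls:
                fh.write(
                    f"{c.chrom}\t{c.start_bp + 1.0:.1f}\t{c.end_bp:.1f}\t{c.sv_type}\t"
                    f"{c.size_delta_bp:.1f}\t{c.zygosity}\t{c.support_count}\t"
                    f"{c.score:.6g}\t{c.module}\t{c.chrom2 or '.'}\t{c.sample_id or '.'}\n"
                )
    elif dialect == "bed":
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tname\tscore\n")
            for c in calls:
                name = f"{c.sv_type};{c.size_delta_bp:.0f};{c.zygosity}"
                fh.write(f"{c.chrom}\t{int(c.start_bp)}\t{int(c.end_bp)}\t{name}\t{c.score:.4g}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_sv_calls(path) -> List[SVCall]:
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != len(_SMAP_COLS):
                raise ParseError(f"{path}:{lineno}: expected {len(_SMAP_COLS)} columns")
            calls.append(
                SVCall(
                    sv_type=f[3], chrom=f[0], start_bp=float(f[1]) - 1.0,
                    end_bp=float(f[2]), size_delta_bp=float(f[4]), zygosity=f[5],
                    support_count=int(f[6]), score=float(f[7]), module=f[8],
                    chrom2=None if f[9] == "." else f[9],
                    sample_id=None if f[10] == "." else f[10],
                )
            )
    return calls


# ---------------------------------------------------------------------------
# BED intervals, cohort metadata, configuration
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read a BED file into a DataFrame with chrom/start/end (+ extra columns)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append(f)
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    ncol = max(len(r) for r in rows)
    names = ["chrom", "start", "end"] + [f"col{i}" for i in range(4, ncol + 1)]
    df = pd.DataFrame([r + [None] * (ncol - len(r)) for r in rows], columns=names)
    df["start"] = df["start"].astype(float).astype(int)
    df["end"] = df["end"].astype(float).astype(int)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            extras = [str(v) for k, v in row.items() if k not in ("chrom", "start", "end")]
            fh.write("\t".join([str(row["chrom"]), str(int(row["start"])), str(int(row["end"]))] + extras) + "\n")


def read_cohort_metadata(path) -> CohortMetadata:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "population", "super_population", "sex"}
    if not required.issubset(df.columns):
        raise ParseError(f"cohort metadata must have columns {sorted(required)}")
    entries = {}
    for _, row in df.iterrows():
        sp = row["super_population"]
        if sp not in CohortMetadata.SUPER_POPULATIONS:
            raise ParseError(f"unknown super-population {sp!r}")
        entries[row["sample_id"]] = {
            "population": row["population"],
            "super_population": sp,
            "sex": row["sex"],
        }
    return CohortMetadata(entries)


def load_config(path) -> dict:
    """Load an INI-style config; values parsed as float where possible."""
    cp = configparser.ConfigParser()
    cp.read(path)
    out = {}
    for section in cp.sections():
        out[section] = {}
        for key, val in cp[section].items():
            try:
                out[section][key] = float(val)
            except ValueError:
                out[section][key] = val
    return out
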
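"""File formats and core containers for SNP panel design.

Markers live in a :class:`MarkerTable` (a thin wrapper over a pandas
DataFrame), genotypes in a :class:`GenotypeMatrix` of minor-allele dosage
codes, genetic maps in a :class:`GeneticMapTrack`, and gene regions in an
:class:`IntervalSet`.

Coordinate conventions: marker positions are 1-based physical bp (as in
VCF/MAP files); intervals are 0-based half-open (BED). A 1-based position
``b`` lies inside ``[s, e)`` iff ``s <= b - 1 < e``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

MISSING: int = -1
"""Sentinel dosage code for a missing genotype call."""

MARKER_COLUMNS = ["marker_id", "chrom", "bp", "allele_minor", "allele_major", "cm", "freq_minor"]


class ParseError(ValueError):
    """Raised when an input file does not parse under the named dialect."""


@dataclass
class MarkerTable:
    """Per-marker metadata: id, autosome, position, alleles, cM, minor-allele frequency.

    The table is kept sorted by (chrom, bp). ``freq_minor`` is folded to
    [0, 0.5]; ``cm`` may be NaN before genetic-map assignment.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in MARKER_COLUMNS if c not in self.df.columns]
        if missing_cols:
            raise ValueError(f"MarkerTable missing columns: {missing_cols}")
        df = self.df.reset_index(drop=True)
        df["chrom"] = df["chrom"].astype(int)
        df["bp"] = df["bp"].astype(np.int64)
        if (df["bp"] < 1).any():
            raise ValueError("marker bp positions must be >= 1")
        if not ((df["chrom"] >= 1) & (df["chrom"] <= 22)).all():
            raise ValueError("chrom must be an autosome label 1-22")
        freq = df["freq_minor"].to_numpy(float)
        ok = np.isnan(freq) | ((freq >= 0.0) & (freq <= 0.5))
        if not ok.all():
            raise ValueError("freq_minor must lie in [0, 0.5] (minor-allele orientation)")
        if not df[["chrom", "bp"]].apply(tuple, axis=1).is_monotonic_increasing:
            raise ValueError("markers must be sorted by (chrom, bp)")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.df["marker_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def bp(self) -> np.ndarray:
        return self.df["bp"].to_numpy()

    @property
    def cm(self) -> np.ndarray:
        return self.df["cm"].to_numpy(float)

    @property
    def freq_minor(self) -> np.ndarray:
        return self.df["freq_minor"].to_numpy(float)

    def take(self, idx) -> "MarkerTable":
        """Subset by positional indices, preserving (chrom, bp) sort order."""
        sub = self.df.iloc[np.sort(np.asarray(idx))].reset_index(drop=True)
        return MarkerTable(sub)

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "MarkerTable":
        df = pd.DataFrame(list(records))
        for col in MARKER_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[MARKER_COLUMNS].sort_values(["chrom", "bp"], kind="stable")
        return cls(df)


@dataclass
class GenotypeMatrix:
    """Samples x markers minor-allele dosage codes with a missing sentinel.

    ``dosages[i, j]`` counts copies of marker j's minor allele carried by
    sample i (0, 1 or 2), or :data:`MISSING`.
    """

    sample_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=np.int8)
        if d.ndim != 2 or d.shape[0] != len(self.sample_ids):
            raise ValueError("dosages must be (n_samples, n_markers)")
        valid = (d == MISSING) | ((d >= 0) & (d <= 2))
        if not valid.all():
            raise ValueError("dosage codes must be in {0,1,2,MISSING}")
        self.dosages = d

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def subset_markers(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.sample_ids, self.dosages[:, np.sort(np.asarray(idx))])

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix([self.sample_ids[i] for i in idx], self.dosages[idx])


@dataclass
class GeneticMapTrack:
    """Per-chromosome sorted (bp, cumulative cM) anchors from a recombination map."""

    anchors: dict[int, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in self.anchors.items():
            bp = np.asarray(bp, dtype=np.int64)
            cm = np.asarray(cm, dtype=float)
            order = np.argsort(bp, kind="stable")
            bp, cm = bp[order], cm[order]
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cumulative cM must be non-decreasing (chrom {chrom})")
            clean[int(chrom)] = (bp, cm)
        self.anchors = clean


@dataclass
class IntervalSet:
    """Per-chromosome merged, sorted 0-based half-open [start, end) intervals."""

    intervals: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged: dict[int, np.ndarray] = {}
        for chrom, arr in self.intervals.items():
            arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if len(arr) == 0:
                continue
            arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
            out = [arr[0].copy()]
            for s, e in arr[1:]:
                if s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append(np.array([s, e]))
            merged[int(chrom)] = np.array(out, dtype=np.int64)
        self.intervals = merged

    def contains(self, chrom: int, bp_1based) -> np.ndarray:
        """Membership of 1-based marker positions in the 0-based intervals."""
        pos = np.atleast_1d(np.asarray(bp_1based, dtype=np.int64)) - 1
        arr = self.intervals.get(int(chrom))
        if arr is None or len(arr) == 0:
            return np.zeros(pos.shape, dtype=bool)
        k = np.searchsorted(arr[:, 0], pos, side="right") - 1
        inside = (k >= 0) & (pos < arr[np.clip(k, 0, None), 1])
        return inside


def _parse_chrom(token: str) -> int:
    token = token.removeprefix("chr")
    try:
        chrom = int(token)
    except ValueError as exc:
        raise ParseError(f"non-autosomal or unparsable chromosome label {token!r}") from exc
    return chrom


# ---------------------------------------------------------------------------
# genotype I/O


def read_genotypes(path: str | os.PathLike, dialect: str) -> tuple[GenotypeMatrix, MarkerTable]:
    """Read genotypes plus marker metadata from one of the supported dialects.

    Dialects: ``ped-map`` (PLINK text PED + MAP sharing a stem), ``vcf``
    (GT field of an uncompressed or bgzipped VCF), ``matrix-tsv`` (markers
    as columns, one row per sample, dosage codes with ``NA`` for missing).

    Dosages are oriented to count the minor allele as estimated from the
    file itself; monomorphic markers get ``freq_minor = 0``.
    """
    if dialect == "ped-map":
        return _read_ped_map(os.fspath(path))
    if dialect == "vcf":
        return _read_vcf(os.fspath(path))
    if dialect == "matrix-tsv":
        return _read_matrix_tsv(os.fspath(path))
    raise ValueError(f"unknown dialect {dialect!r}")


def _orient_minor(dosages: np.ndarray, a1: list[str], a2: list[str]) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Flip columns so codes count the minor allele; returns folded frequencies."""
    d = dosages.astype(np.int8)
    called = d != MISSING
    n_called = called.sum(axis=0)
    alt_count = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt_count / np.maximum(2 * n_called, 1), np.nan)
    flip = freq > 0.5
    minor = list(a1)
    major = list(a2)
    for j in np.flatnonzero(flip):
        col = d[:, j]
        d[:, j] = np.where(col == MISSING, MISSING, 2 - col)
        minor[j], major[j] = major[j], minor[j]
        freq[j] = 1.0 - freq[j]
    return d, freq, minor, major


def _read_ped_map(path: str) -> tuple[GenotypeMatrix, MarkerTable]:
    stem, ext = os.path.splitext(path)
    ped_path = path if ext == ".ped" else stem + ".ped"
    map_path = stem + ".map"
    markers = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 MAP columns")
            chrom = _parse_chrom(fields[0])
            markers.append((chrom, fields[1], float(fields[2]), int(fields[3])))
    n_m = len(markers)
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    allele_sets: list[dict[str, int]] = [dict() for _ in range(n_m)]
    raw_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_m:
                raise ParseError(f"{ped_path}:{lineno}: expected {6 + 2 * n_m} PED columns, got {len(fields)}")
            sample_ids.append(fields[1])
            pairs = []
            for j in range(n_m):
                a, b = fields[6 + 2 * j], fields[7 + 2 * j]
                pairs.append((a, b))
                for al in (a, b):
                    if al != "0":
                        allele_sets[j][al] = allele_sets[j].get(al, 0) + 1
            raw_pairs.append(pairs)
    for j, counts in enumerate(allele_sets):
        if len(counts) > 2:
            raise ParseError(f"marker {markers[j][1]} is not bi-allelic: alleles {sorted(counts)}")
    # per-marker reference = most frequent allele present; dosage counts the other
    a_ref: list[str] = []
    a_alt: list[str] = []
    for counts in allele_sets:
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ordered) == 0:
            a_ref.append("N")
            a_alt.append("N")
        elif len(ordered) == 1:
            a_ref.append(ordered[0][0])
            a_alt.append("N")
        else:
            a_ref.append(ordered[0][0])
            a_alt.append(ordered[1][0])
    for pairs in raw_pairs:
        row = np.full(n_m, MISSING, dtype=np.int8)
        for j, (a, b) in enumerate(pairs):
            if a == "0" or b == "0":
                continue
            row[j] = (a == a_alt[j]) + (b == a_alt[j])
        rows.append(row)
    dosages = np.array(rows, dtype=np.int8) if rows else np.empty((0, n_m), dtype=np.int8)
    d, freq, minor, major = _orient_minor(dosages, a_alt, a_ref)
    records = [
        {"marker_id": mid, "chrom": chrom, "bp": bp, "allele_minor": minor[j],
         "allele_major": major[j], "cm": cm if cm > 0 else np.nan,
         "freq_minor": 0.0 if np.isnan(freq[j]) else freq[j]}
        for j, (chrom, mid, cm, bp) in enumerate(markers)
    ]
    table = MarkerTable.from_records(records)
    order = _marker_order(markers)
    return GenotypeMatrix(sample_ids, d[:, order]), table


def _marker_order(markers) -> np.ndarray:
    keys = [(chrom, bp) for chrom, _, _, bp in markers]
    return np.array(sorted(range(len(keys)), key=keys.__getitem__), dtype=np.intp)


def _read_vcf(path: str) -> tuple[GenotypeMatrix, MarkerTable]:
    import pysam

    with pysam.VariantFile(path) as vcf:
        sample_ids = list(vcf.header.samples)
        records = []
        rows = []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                raise ParseError(f"site {rec.id or rec.pos} is not bi-allelic SNP: {rec.ref}/{rec.alts}")
            chrom = _parse_chrom(rec.chrom)
            dos = np.full(len(sample_ids), MISSING, dtype=np.int8)
            for i, sample in enumerate(rec.samples.values()):
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                dos[i] = sum(gt)
            rows.append(dos)
            records.append((chrom, rec.id or f"{chrom}:{rec.pos}", rec.pos, rec.ref, rec.alts[0]))
    dosages = np.array(rows, dtype=np.int8).T if rows else np.empty((len(sample_ids), 0), dtype=np.int8)
    alt = [r[4] for r in records]
    ref = [r[3] for r in records]
    d, freq, minor, major = _orient_minor(dosages, alt, ref)
    table_records = [
        {"marker_id": mid, "chrom": chrom, "bp": pos, "allele_minor": minor[j],
         "allele_major": major[j], "cm": np.nan,
         "freq_minor": 0.0 if np.isnan(freq[j]) else freq[j]}
        for j, (chrom, mid, pos, _, _) in enumerate(records)
    ]
    table = MarkerTable.from_records(table_records)
    order = np.array(sorted(range(len(records)), key=lambda j: (records[j][0], records[j][2])), dtype=np.intp)
    return GenotypeMatrix(sample_ids, d[:, order]), table


def _read_matrix_tsv(path: str) -> tuple[GenotypeMatrix, MarkerTable]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    meta_cols = {"marker_id", "chrom", "bp", "allele_minor", "allele_major"}
    if not meta_cols.issubset(df.columns[:5]):
        raise ParseError("matrix-tsv requires marker_id/chrom/bp/allele_minor/allele_major header rows transposed")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    dosages = df[sample_cols].replace("NA", str(MISSING)).to_numpy(dtype=np.int8).T
    a_min = df["allele_minor"].tolist()
    a_maj = df["allele_major"].tolist()
    d, freq, minor, major = _orient_minor(dosages, a_min, a_maj)
    records = [
        {"marker_id": df["marker_id"].iat[j], "chrom": _parse_chrom(df["chrom"].iat[j]),
         "bp": int(df["bp"].iat[j]), "allele_minor": minor[j], "allele_major": major[j],
         "cm": np.nan, "freq_minor": 0.0 if np.isnan(freq[j]) else freq[j]}
        for j in range(len(df))
    ]
    table = MarkerTable.from_records(records)
    keys = [(r["chrom"], r["bp"]) for r in records]
    order = np.array(sorted(range(len(keys)), key=keys.__getitem__), dtype=np.intp)
    return GenotypeMatrix(sample_cols, d[:, order]), table


def write_matrix_tsv(path: str | os.PathLike, g: GenotypeMatrix, markers: MarkerTable) -> None:
    """Write the transposed dosage-matrix dialect read by ``matrix-tsv``."""
    out = markers.df[["marker_id", "chrom", "bp", "allele_minor", "allele_major"]].copy()
    for i, sid in enumerate(g.sample_ids):
        col = g.dosages[:, :][i].astype(object)
        out[sid] = [("NA" if v == MISSING else int(v)) for v in col]
    out.to_csv(path, sep="\t", index=False)


def write_ped_map(prefix: str | os.PathLike, g: GenotypeMatrix, markers: MarkerTable) -> None:
    """Write PLINK-style text PED/MAP files (alleles from the marker table)."""
    prefix = os.fspath(prefix)
    df = markers.df
    with open(prefix + ".map", "w") as fh:
        for _, row in df.iterrows():
            cm = 0.0 if pd.isna(row["cm"]) else float(row["cm"])
            fh.write(f"{row['chrom']}\t{row['marker_id']}\t{cm}\t{row['bp']}\n")
    minor = df["allele_minor"].tolist()
    major = df["allele_major"].tolist()
    with open(prefix + ".ped", "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            fields = [f"F{i}", sid, "0", "0", "0", "-9"]
            for j, d in enumerate(g.dosages[i]):
                if d == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [minor[j]] * int(d) + [major[j]] * (2 - int(d))
            fh.write(" ".join(fields) + "\n")


def write_vcf(path: str | os.PathLike, g: GenotypeMatrix, markers: MarkerTable) -> None:
    """Write a minimal VCF (GT only); minor allele is emitted as ALT."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in sorted(set(markers.chrom.tolist())):
        header.contigs.add(str(chrom))
    for sid in g.sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as vcf:
        df = markers.df
        for j in range(len(df)):
            rec = vcf.new_record(
                contig=str(df["chrom"].iat[j]), start=int(df["bp"].iat[j]) - 1,
                stop=int(df["bp"].iat[j]), alleles=(df["allele_major"].iat[j], df["allele_minor"].iat[j]),
                id=str(df["marker_id"].iat[j]),
            )
            for i, sid in enumerate(g.sample_ids):
                d = int(g.dosages[i, j])
                rec.samples[sid]["GT"] = (None, None) if d == MISSING else ((0, 0), (0, 1), (1, 1))[d]
            vcf.write(rec)


# ---------------------------------------------------------------------------
# genetic map


def read_genetic_map(path: str | os.PathLike) -> GeneticMapTrack:
    """Read a 1000G-style recombination map.

    Expected columns per chromosome block: chromosome, position (bp),
    rate (cM/Mb, ignored), cumulative cM. A header line is skipped if the
    position column is non-numeric.
    """
    anchors: dict[int, list[tuple[int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            try:
                chrom = _parse_chrom(fields[0])
                bp = int(fields[1])
                cm = float(fields[3]) if len(fields) > 3 else float(fields[2])
            except (ParseError, ValueError):
                if lineno == 1:
                    continue  # header
                raise ParseError(f"{path}:{lineno}: unparsable genetic-map line")
            anchors.setdefault(chrom, []).append((bp, cm))
    return GeneticMapTrack({c: (np.array([a for a, _ in v]), np.array([b for _, b in v]))
                            for c, v in anchors.items()})


def assign_cm(markers: MarkerTable, gmap: GeneticMapTrack, interpolate: bool = True) -> MarkerTable:
    """Assign cumulative cM positions to markers from a genetic map.

    Markers at an anchor get the anchor's cM. In-range markers are linearly
    interpolated when ``interpolate`` is true; otherwise, and always outside
    the anchored range, the nearest anchor by physical distance is used
    (ties resolve to the lower bp anchor).
    """
    df = markers.df.copy()
    cm_out = np.empty(len(df), dtype=float)
    for chrom in np.unique(markers.chrom):
        sel = np.flatnonzero(markers.chrom == chrom)
        if int(chrom) not in gmap.anchors:
            bad = df["marker_id"].iloc[sel].tolist()
            raise ValueError(f"chromosome {chrom} absent from genetic map; affected markers: {bad}")
        a_bp, a_cm = gmap.anchors[int(chrom)]
        pos = markers.bp[sel]
        if interpolate:
            vals = np.interp(pos, a_bp, a_cm)
            below = pos < a_bp[0]
            above = pos > a_bp[-1]
            vals[below] = a_cm[0]
            vals[above] = a_cm[-1]
        else:
            right = np.searchsorted(a_bp, pos, side="left")
            left = np.clip(right - 1, 0, len(a_bp) - 1)
            right = np.clip(right, 0, len(a_bp) - 1)
            d_left = np.abs(pos - a_bp[left])
            d_right = np.abs(a_bp[right] - pos)
            use_left = d_left <= d_right  # tie -> lower bp
            vals = np.where(use_left, a_cm[left], a_cm[right])
        cm_out[sel] = vals
    df["cm"] = cm_out
    return MarkerTable(df)


# ---------------------------------------------------------------------------
# intervals and frequency tables


def read_intervals(path: str | os.PathLike) -> IntervalSet:
    """Read a BED-like 3+ column interval file (0-based half-open)."""
    per_chrom: dict[int, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = _parse_chrom(fields[0])
            start, end = int(fields[1]), int(fields[2])
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            per_chrom.setdefault(chrom, []).append((start, end))
    return IntervalSet({c: np.array(v, dtype=np.int64) for c, v in per_chrom.items()})


def write_intervals(path: str | os.PathLike, intervals: IntervalSet) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals.intervals):
            for s, e in intervals.intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_frequency_table(path: str | os.PathLike) -> MarkerTable:
    """Read a tab-separated allele-frequency table into a MarkerTable."""
    df = pd.read_csv(path, sep="\t")
    rename = {"minor": "allele_minor", "major": "allele_major", "freq": "freq_minor"}
    df = df.rename(columns=rename)
    for col in MARKER_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[MARKER_COLUMNS].sort_values(["chrom", "bp"], kind="stable")
    return MarkerTable(df)


def write_frequency_table(path: str | os.PathLike, markers: MarkerTable) -> None:
    markers.df.to_csv(path, sep="\t", index=False, float_format="%.10g")
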
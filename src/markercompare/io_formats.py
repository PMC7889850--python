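"""Readers, writers and core table types for the marker-comparison pipeline.

Two marker representations are supported: binary presence/absence
fingerprint tables (dominant markers, one 0/1 column per scored band) and
diploid SNP dosage matrices (0/1/2 with an explicit missing sentinel).
Sample metadata carries the region label used as the grouping prior, the
replicate structure used by the QC stage, and an optional ``match_key``
that joins individuals across the two marker types.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing dosage call.  Never conflated with dosage 0.
MISSING: int = -1

#: Default primer-combination tag used when a table does not carry tags.
DEFAULT_COMBO: str = "combo1"

_DELIMITERS = ("\t", ",", ";")


class FormatError(ValueError):
    """Raised when an on-disk table violates the expected dialect."""


def _sniff_delimiter(first_line: str) -> str:
    counts = {d: first_line.count(d) for d in _DELIMITERS}
    best = max(counts, key=lambda d: counts[d])
    return best if counts[best] > 0 else "\t"


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} id: {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class BinaryMarkerMatrix:
    """Samples x loci presence/absence table with per-locus combo tags."""

    sample_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray  # (n_samples, n_loci), int8, entries in {0, 1}
    primer_combo: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.locus_ids, "locus")
        if self.values.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise FormatError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise FormatError("binary marker matrix entries must be 0 or 1")
        if not self.primer_combo:
            self.primer_combo = {l: DEFAULT_COMBO for l in self.locus_ids}
        missing_tags = [l for l in self.locus_ids if l not in self.primer_combo]
        if missing_tags:
            raise FormatError(f"loci without primer-combo tag: {missing_tags[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]

    def subset_loci(self, locus_ids: Sequence[str]) -> "BinaryMarkerMatrix":
        idx = [self.locus_ids.index(l) for l in locus_ids]
        return BinaryMarkerMatrix(
            sample_ids=list(self.sample_ids),
            locus_ids=list(locus_ids),
            values=self.values[:, idx].copy(),
            primer_combo={l: self.primer_combo[l] for l in locus_ids},
        )

    def drop_samples(self, sample_ids: Iterable[str]) -> "BinaryMarkerMatrix":
        drop = set(sample_ids)
        keep = [i for i, s in enumerate(self.sample_ids) if s not in drop]
        return BinaryMarkerMatrix(
            sample_ids=[self.sample_ids[i] for i in keep],
            locus_ids=list(self.locus_ids),
            values=self.values[keep].copy(),
            primer_combo=dict(self.primer_combo),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "BinaryMarkerMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return BinaryMarkerMatrix(
            sample_ids=list(sample_ids),
            locus_ids=list(self.locus_ids),
            values=self.values[idx].copy(),
            primer_combo=dict(self.primer_combo),
        )

    def split_by_combo(self) -> dict[str, "BinaryMarkerMatrix"]:
        """Partition loci by primer-combination tag (stable locus order)."""
        out: dict[str, BinaryMarkerMatrix] = {}
        for combo in dict.fromkeys(self.primer_combo[l] for l in self.locus_ids):
            loci = [l for l in self.locus_ids if self.primer_combo[l] == combo]
            out[combo] = self.subset_loci(loci)
        return out


@dataclass
class GenotypeMatrix:
    """Samples x loci diploid dosage table; MISSING marks no-calls."""

    sample_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray  # (n_samples, n_loci), int8, entries in {0,1,2,MISSING}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.locus_ids, "locus")
        if self.values.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise FormatError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if not np.isin(self.values, (0, 1, 2, MISSING)).all():
            raise FormatError("dosages must be 0, 1, 2 or the MISSING sentinel")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_fraction_per_locus(self) -> np.ndarray:
        return (self.values == MISSING).mean(axis=0)

    def subset_loci_idx(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            locus_ids=[self.locus_ids[i] for i in idx],
            values=self.values[:, idx].copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            locus_ids=list(self.locus_ids),
            values=self.values[idx].copy(),
        )


@dataclass
class SampleMetadata:
    """Per-sample region labels, replicate links and cross-marker join keys."""

    samples: list[str]
    region: dict[str, str]
    replicate_of: dict[str, str] = field(default_factory=dict)
    match_key: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.samples, "sample")
        sset = set(self.samples)
        for rep, src in self.replicate_of.items():
            if src not in sset:
                raise FormatError(
                    f"replicate_of link {rep!r} -> {src!r}: target not in metadata"
                )

    def replicate_pairs(self) -> list[tuple[str, str]]:
        """(source, replicate) pairs in metadata order."""
        return [(src, rep) for rep, src in self.replicate_of.items()]

    def replicate_samples(self) -> list[str]:
        return list(self.replicate_of)

    def groups_for(self, sample_ids: Sequence[str]) -> dict[str, str]:
        return {s: self.region[s] for s in sample_ids}


@dataclass
class DistanceMatrix:
    """Labelled symmetric dissimilarity matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.labels, "label")
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise FormatError(f"distance matrix shape {self.values.shape} != ({n},{n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise FormatError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise FormatError("distance matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise FormatError("distance matrix has negative entries")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        iu, ju = np.triu_indices(self.n, 1)
        return self.values[iu, ju]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        if set(labels) != set(self.labels):
            missing = sorted(set(labels) - set(self.labels))
            extra = sorted(set(self.labels) - set(labels))
            raise FormatError(
                f"label mismatch: missing {missing}, unexpected {extra}"
            )
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)].copy())

    def relabel(self, mapping: Mapping[str, str]) -> "DistanceMatrix":
        return DistanceMatrix(
            [mapping.get(l, l) for l in self.labels], self.values.copy()
        )


# ---------------------------------------------------------------------------
# Binary marker tables
# ---------------------------------------------------------------------------


def read_binary_marker_table(
    path: str | Path, delimiter: str | None = None
) -> BinaryMarkerMatrix:
    """Read a 0/1 marker table.

    Layout: header row of locus ids (optionally ``comboTag:locusName``),
    leading column of sample ids, cells strictly ``0`` or ``1``.
    The delimiter is sniffed among tab/comma/semicolon unless given.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: need a header row and at least one sample row")
    sep = delimiter or _sniff_delimiter(lines[0])
    header = next(csv.reader([lines[0]], delimiter=sep))
    locus_tokens = [h.strip() for h in header[1:]]
    locus_ids: list[str] = []
    primer_combo: dict[str, str] = {}
    for tok in locus_tokens:
        if ":" in tok:
            combo, name = tok.split(":", 1)
        else:
            combo, name = DEFAULT_COMBO, tok
        locus_ids.append(name)
        primer_combo[name] = combo
    sample_ids: list[str] = []
    rows: list[list[int]] = []
    for line in lines[1:]:
        cells = next(csv.reader([line], delimiter=sep))
        sid = cells[0].strip()
        if len(cells) - 1 != len(locus_ids):
            raise FormatError(
                f"{path}: sample {sid!r} has {len(cells) - 1} cells, "
                f"expected {len(locus_ids)}"
            )
        row: list[int] = []
        for locus, cell in zip(locus_ids, cells[1:]):
            v = cell.strip()
            if v not in ("0", "1"):
                raise FormatError(
                    f"{path}: non-binary value {cell!r} at sample {sid!r}, "
                    f"locus {locus!r}"
                )
            row.append(int(v))
        sample_ids.append(sid)
        rows.append(row)
    try:
        return BinaryMarkerMatrix(sample_ids, locus_ids, np.array(rows), primer_combo)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_binary_marker_table(
    m: BinaryMarkerMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["sample"] + [f"{m.primer_combo[l]}:{l}" for l in m.locus_ids])
        for sid, row in zip(m.sample_ids, m.values):
            w.writerow([sid] + [int(v) for v in row])


# ---------------------------------------------------------------------------
# Genotype matrices
# ---------------------------------------------------------------------------


def read_genotype_table(
    path: str | Path,
    format: str = "dosage_table",
    delimiter: str | None = None,
) -> GenotypeMatrix:
    """Read a SNP genotype matrix.

    ``dosage_table``: one row per individual, entries in {0,1,2,NA}.
    ``structure_tworow``: two consecutive rows per individual carrying
    integer allele codes, -9 = missing.  Rows are collapsed to dosage
    relative to the numerically lowest allele code observed at each locus;
    a -9 in either row yields MISSING.
    """
    if format == "dosage_table":
        return _read_dosage_table(path, delimiter)
    if format == "structure_tworow":
        return _read_structure_tworow(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_dosage_table(path: str | Path, delimiter: str | None) -> GenotypeMatrix:
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: need a header row and at least one sample row")
    sep = delimiter or _sniff_delimiter(lines[0])
    header = next(csv.reader([lines[0]], delimiter=sep))
    locus_ids = [h.strip() for h in header[1:]]
    sample_ids: list[str] = []
    rows: list[list[int]] = []
    for line in lines[1:]:
        cells = next(csv.reader([line], delimiter=sep))
        sid = cells[0].strip()
        if len(cells) - 1 != len(locus_ids):
            raise FormatError(
                f"{path}: sample {sid!r} has {len(cells) - 1} cells, "
                f"expected {len(locus_ids)}"
            )
        row = []
        for locus, cell in zip(locus_ids, cells[1:]):
            v = cell.strip()
            if v in ("NA", "na", ""):
                row.append(MISSING)
            elif v in ("0", "1", "2"):
                row.append(int(v))
            else:
                raise FormatError(
                    f"{path}: invalid dosage {cell!r} at sample {sid!r}, "
                    f"locus {locus!r}"
                )
        sample_ids.append(sid)
        rows.append(row)
    try:
        return GenotypeMatrix(sample_ids, locus_ids, np.array(rows))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _read_structure_tworow(path: str | Path) -> GenotypeMatrix:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    # Optional header of locus ids: present iff the first line has one fewer
    # field than the following data lines (no leading sample-id column).
    first = lines[0].split()
    second = lines[1].split() if len(lines) > 1 else []
    if second and len(first) == len(second) - 1:
        locus_ids = first
        data_lines = lines[1:]
    else:
        locus_ids = None
        data_lines = lines
    if len(data_lines) % 2 != 0:
        raise FormatError(
            f"{path}: structure_tworow requires an even number of genotype rows, "
            f"got {len(data_lines)}"
        )
    sample_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    for ln in data_lines:
        fields = ln.split()
        sample_ids.append(fields[0])
        try:
            allele_rows.append(np.array([int(x) for x in fields[1:]]))
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer allele code in row for "
                              f"{fields[0]!r}") from exc
    n_loci = len(allele_rows[0])
    if locus_ids is None:
        locus_ids = [f"locus{i + 1}" for i in range(n_loci)]
    if any(len(r) != n_loci for r in allele_rows):
        raise FormatError(f"{path}: ragged allele rows")
    individuals: list[str] = []
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(0, len(data_lines), 2):
        if sample_ids[i] != sample_ids[i + 1]:
            raise FormatError(
                f"{path}: consecutive rows {sample_ids[i]!r} / {sample_ids[i + 1]!r} "
                "do not repeat the same individual id"
            )
        individuals.append(sample_ids[i])
        pairs.append((allele_rows[i], allele_rows[i + 1]))
    a1 = np.stack([p[0] for p in pairs])
    a2 = np.stack([p[1] for p in pairs])
    dosage = np.full(a1.shape, MISSING, dtype=np.int8)
    for j in range(n_loci):
        col = np.concatenate([a1[:, j], a2[:, j]])
        codes = np.unique(col[col != -9])
        if codes.size > 2:
            raise FormatError(
                f"{path}: locus {locus_ids[j]!r} has {codes.size} allele codes "
                f"({codes.tolist()}); only biallelic loci are supported"
            )
        if codes.size == 0:
            continue  # all missing
        ref = codes.min()
        obs = (a1[:, j] != -9) & (a2[:, j] != -9)
        dosage[obs, j] = (a1[obs, j] == ref).astype(np.int8) + (
            a2[obs, j] == ref
        ).astype(np.int8)
    try:
        return GenotypeMatrix(individuals, list(locus_ids), dosage)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_genotype_table(
    g: GenotypeMatrix,
    path: str | Path,
    format: str = "dosage_table",
    delimiter: str = ",",
) -> None:
    """Write a genotype matrix; MISSING becomes NA (dosage) or -9 (structure)."""
    if format == "dosage_table":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
            w.writerow(["sample"] + g.locus_ids)
            for sid, row in zip(g.sample_ids, g.values):
                w.writerow([sid] + ["NA" if v == MISSING else int(v) for v in row])
    elif format == "structure_tworow":
        # Dosage d -> d copies of code 1 and (2-d) of code 2.  Loci where
        # code 1 is never observed read back polarity-flipped (documented).
        with open(path, "w") as fh:
            fh.write(" ".join(g.locus_ids) + "\n")
            for sid, row in zip(g.sample_ids, g.values):
                r1 = ["-9" if v == MISSING else ("1" if v >= 1 else "2") for v in row]
                r2 = ["-9" if v == MISSING else ("1" if v == 2 else "2") for v in row]
                fh.write(sid + " " + " ".join(r1) + "\n")
                fh.write(sid + " " + " ".join(r2) + "\n")
    else:
        raise ValueError(f"unknown genotype format: {format!r}")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------


def read_sample_metadata(
    path: str | Path, region_regex: str | None = None
) -> SampleMetadata:
    """Read a metadata CSV with columns sample, region, replicate_of, match_key.

    ``region_regex``, if given, extracts the region from the sample id
    (first capture group) for rows with an empty region column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"sample", "region"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: metadata needs columns {sorted(required)}")
    samples = [s.strip() for s in df["sample"]]
    region: dict[str, str] = {}
    for sid, reg in zip(samples, df["region"]):
        reg = reg.strip()
        if not reg and region_regex:
            m = re.search(region_regex, sid)
            if m:
                reg = m.group(1)
        if not reg:
            raise FormatError(f"{path}: sample {sid!r} has no region label")
        region[sid] = reg
    replicate_of: dict[str, str] = {}
    if "replicate_of" in df.columns:
        for sid, src in zip(samples, df["replicate_of"]):
            if src.strip():
                replicate_of[sid] = src.strip()
    match_key: dict[str, str] = {}
    if "match_key" in df.columns:
        for sid, mk in zip(samples, df["match_key"]):
            if mk.strip():
                match_key[sid] = mk.strip()
    try:
        return SampleMetadata(samples, region, replicate_of, match_key)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["sample", "region", "replicate_of", "match_key"])
        for s in meta.samples:
            w.writerow(
                [
                    s,
                    meta.region[s],
                    meta.replicate_of.get(s, ""),
                    meta.match_key.get(s, ""),
                ]
            )


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix([str(c) for c in df.columns], df.to_numpy(dtype=float))


def write_distance_matrix(d: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(d.values, index=d.labels, columns=d.labels).to_csv(path)


# ---------------------------------------------------------------------------
# Missingness filter
# ---------------------------------------------------------------------------


def filter_loci_by_missingness(
    gm: GenotypeMatrix, max_missing: float
) -> GenotypeMatrix:
    """Drop loci whose missing-call fraction exceeds ``max_missing``.

    Retains relative locus order and the full sample set; a locus is kept
    iff its missing fraction is <= max_missing (strictly-more-than rule).
    """
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError(f"max_missing must be in [0, 1], got {max_missing}")
    frac = gm.missing_fraction_per_locus()
    keep = np.flatnonzero(frac <= max_missing)
    if keep.size == gm.n_loci:
        return gm
    logger.info(
        "missingness filter: removed %d of %d loci at threshold %.3f",
        gm.n_loci - keep.size, gm.n_loci, max_missing,
    )
    return gm.subset_loci_idx(keep)
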
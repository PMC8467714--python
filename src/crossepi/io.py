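"""Reading and writing genotype, phenotype and map tables, plus marker QC.

All formats are plain text.  Genotypes travel as TSV (one row per
individual, codes 0/1/2 counting the non-reference strain allele, NA for
missing) or as PLINK-style PED/MAP with strain-letter allele pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MISSING, Marker, MarkerMap

__all__ = [
    "GenotypeTable",
    "read_genotypes",
    "write_genotypes",
    "qc_filter_markers",
    "read_marker_map",
    "write_marker_map",
    "read_phenotypes",
    "write_phenotypes",
    "phenotype_frame",
]

_VALID_CODES = {"0": 0, "1": 1, "2": 2, "NA": MISSING}


@dataclass
class GenotypeTable:
    """Rectangular individuals-by-markers genotype matrix."""

    ids: list[str]
    markers: list[str]
    codes: np.ndarray  # (n, m) int8 with -1 missing

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.ids), len(self.markers)):
            raise ValueError("codes shape does not match ids x markers")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker ids")
        valid = np.isin(self.codes, [MISSING, 0, 1, 2])
        if not valid.all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return len(self.markers)

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing genotypes."""
        if self.n == 0:
            return np.zeros(self.m)
        return (self.codes == MISSING).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency over observed genotypes."""
        out = np.full(self.m, np.nan)
        for j in range(self.m):
            col = self.codes[:, j]
            obs = col[col != MISSING]
            if obs.size:
                f = obs.mean() / 2.0
                out[j] = min(f, 1.0 - f)
        return out


def write_genotypes(table: GenotypeTable, path: str | Path,
                    dialect: str = "tsv",
                    marker_map: MarkerMap | None = None,
                    alleles: tuple[str, str] = ("B", "X")) -> None:
    """Write a genotype table as TSV or PED/MAP.

    For ``dialect="ped-map"``, ``path`` is a basename: ``<path>.ped`` and
    ``<path>.map`` are written and a marker map is required.  Codes map to
    allele pairs (0 -> "B B", 1 -> "B X", 2 -> "X X", missing -> "0 0").
    """
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(table.markers) + "\n")
            for i, ind in enumerate(table.ids):
                row = ["NA" if c == MISSING else str(int(c))
                       for c in table.codes[i]]
                fh.write(ind + "\t" + "\t".join(row) + "\n")
    elif dialect == "ped-map":
        if marker_map is None:
            raise ValueError("ped-map export requires a marker map")
        if marker_map.ids != table.markers:
            raise ValueError("marker map does not match table markers")
        a, b = alleles
        pair = {0: f"{a} {a}", 1: f"{a} {b}", 2: f"{b} {b}", MISSING: "0 0"}
        with open(path.with_suffix(".ped"), "w") as fh:
            for i, ind in enumerate(table.ids):
                fields = ["FAM", ind, "0", "0", "0", "-9"]
                fields += [pair[int(c)] for c in table.codes[i]]
                fh.write(" ".join(fields) + "\n")
        with open(path.with_suffix(".map"), "w") as fh:
            for mk in marker_map.markers:
                fh.write(f"{mk.chrom}\t{mk.id}\t{mk.cm}\t{mk.bp}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_genotypes(path: str | Path, dialect: str = "tsv",
                   alleles: tuple[str, str] = ("B", "X")) -> GenotypeTable:
    """Read a genotype table; malformed rows are rejected with their line number."""
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "ped-map":
        return _read_ped(path, alleles)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path: Path) -> GenotypeTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "id":
            raise ValueError(f"{path}: first header field must be 'id'")
        markers = header[1:]
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(markers) + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(markers) + 1} fields, "
                    f"got {len(fields)}")
            ids.append(fields[0])
            try:
                rows.append([_VALID_CODES[f] for f in fields[1:]])
            except KeyError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: unknown genotype code {exc.args[0]!r}"
                ) from None
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"{path}: duplicate individual id {dup!r}")
    codes = np.asarray(rows, dtype=np.int8) if rows else \
        np.empty((0, len(markers)), dtype=np.int8)
    return GenotypeTable(ids=ids, markers=markers, codes=codes)


def _read_ped(path: Path, alleles: tuple[str, str]) -> GenotypeTable:
    path = Path(path)
    map_path = path.with_suffix(".map")
    ped_path = path.with_suffix(".ped")
    markers = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"{map_path}: line {lineno}: expected 4 fields")
            markers.append(fields[1])
    a, b = alleles
    decode = {(a, a): 0, (a, b): 1, (b, a): 1, (b, b): 2, ("0", "0"): MISSING}
    ids, rows = [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if len(fields) != 6 + 2 * len(markers):
                raise ValueError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * len(markers)} "
                    f"fields, got {len(fields)}")
            ids.append(fields[1])
            row = []
            for j in range(len(markers)):
                key = (fields[6 + 2 * j], fields[7 + 2 * j])
                if key not in decode:
                    raise ValueError(
                        f"{ped_path}: line {lineno}: unknown allele pair {key}")
                row.append(decode[key])
            rows.append(row)
    if len(set(ids)) != len(ids):
        raise ValueError(f"{ped_path}: duplicate individual ids")
    codes = np.asarray(rows, dtype=np.int8) if rows else \
        np.empty((0, len(markers)), dtype=np.int8)
    return GenotypeTable(ids=ids, markers=markers, codes=codes)


def qc_filter_markers(table: GenotypeTable, max_missing: float = 0.10
                      ) -> tuple[GenotypeTable, pd.DataFrame]:
    """Drop markers whose missing fraction strictly exceeds ``max_missing``.

    Returns the filtered table and a QC report listing every marker with
    its missing fraction, minor allele frequency, and drop status.  The
    boundary is strict: a marker missing exactly ``max_missing`` is kept.
    The report schema leaves room for additional criteria.
    """
    frac = table.missing_fraction()
    maf = table.maf()
    dropped = frac > max_missing
    report = pd.DataFrame({
        "marker": table.markers,
        "missing_fraction": frac,
        "maf": maf,
        "dropped": dropped,
        "reason": np.where(dropped, f"missing>{max_missing:g}", ""),
    })
    keep = ~dropped
    filtered = GenotypeTable(
        ids=list(table.ids),
        markers=[m for m, k in zip(table.markers, keep) if k],
        codes=table.codes[:, keep])
    return filtered, report


def write_marker_map(marker_map: MarkerMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\tchrom\tbp\tcm\n")
        for m in marker_map.markers:
            fh.write(f"{m.id}\t{m.chrom}\t{m.bp}\t{m.cm:.6g}\n")


def read_marker_map(path: str | Path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t")
    markers = tuple(Marker(str(r.marker), int(r.chrom), int(r.bp), float(r.cm))
                    for r in df.itertuples())
    return MarkerMap(markers)


def phenotype_frame(cohort) -> pd.DataFrame:
    """Per-individual phenotype table with one binary column per defect.

    For mutants, a defect column is 1 for that defect, 0 for normal, and
    NA when the individual carries a different defect (it is excluded from
    that defect's case-control analysis).  Wild types are NA throughout.
    """
    defects = cohort.defect_labels()
    df = pd.DataFrame({
        "id": cohort.ids,
        "cross": cohort.cross,
        "generation": cohort.generation,
        "mutant": cohort.mutant.astype(int),
    })
    for d in defects:
        col = np.full(cohort.n, np.nan)
        is_case = cohort.phenotype == d
        is_ctrl = cohort.phenotype == "normal"
        col[cohort.mutant & is_case] = 1
        col[cohort.mutant & is_ctrl] = 0
        df[d] = col
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str | Path, genotype_ids: list[str] | None = None
                    ) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    required = {"id", "cross", "generation", "mutant"}
    if not required <= set(df.columns):
        raise ValueError(f"phenotype table must have columns {sorted(required)}")
    if genotype_ids is not None:
        missing = set(df["id"]) - set(genotype_ids)
        if missing:
            raise ValueError(
                f"phenotyped ids absent from genotype table: {sorted(missing)[:5]}")
    return df
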
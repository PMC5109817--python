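"""Domain containers for a germplasm collection and delimited-text I/O.

The central object is the :class:`GenotypeMatrix`: diploid, unphased calls
(unordered allele pairs) for a set of accessions across a panel of markers,
with missingness as a first-class state.  Phenotypes are a mix of
qualitative traits (named classes) and quantitative traits (finite reals);
passport data carries species and origin labels.  Nothing in the pipeline
ever imputes a missing value — every statistic downstream defines its own
denominator over the non-missing entries.

Exchange formats are deliberately plain: a comma-delimited genotype matrix
("matrix-csv", first header cell ``accession``, cells like ``A/B`` or
``./.``), a phenotype CSV paired with a JSON trait schema, and a passport
CSV.  A VCF import (GT fields only) is available when pysam is installed.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MISSING = None

#: encodings accepted as a missing genotype call in matrix-csv cells
_MISSING_TOKENS = {"./.", "NN", "", ".", "N/N"}


class FormatError(ValueError):
    """A file or in-memory table violates the expected layout or content."""


class UndefinedValueError(ValueError):
    """A statistic has an empty denominator (e.g. an all-missing accession)."""


def normalize_call(a: str, b: str) -> tuple[str, str]:
    """Return the unordered call (a, b) in canonical (lexicographic) order."""
    return (a, b) if a <= b else (b, a)


@dataclass
class GenotypeMatrix:
    """Diploid calls for accessions x markers with a missing mask.

    ``calls`` is an (n_accessions, n_markers) object array whose cells are
    either a lexicographically ordered ``(allele, allele)`` tuple or
    ``None`` (missing).  Phase is never represented: ``A/B`` and ``B/A``
    are the same call.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray  # object array of tuple[str, str] | None

    def __post_init__(self) -> None:
        for name, ids in (("accession", self.accession_ids), ("marker", self.marker_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise FormatError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        self.calls = np.asarray(self.calls, dtype=object)
        if self.calls.shape != (len(self.accession_ids), len(self.marker_ids)):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {len(self.marker_ids)} markers"
            )
        self._acc_index = {a: i for i, a in enumerate(self.accession_ids)}
        self._marker_index = {m: j for j, m in enumerate(self.marker_ids)}

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def accession_index(self, accession_id: str) -> int:
        try:
            return self._acc_index[accession_id]
        except KeyError:
            raise KeyError(f"unknown accession id: {accession_id!r}") from None

    def marker_alleles(self, marker_id: str) -> list[str]:
        """Sorted distinct alleles observed at a marker (may be empty)."""
        j = self._marker_index[marker_id]
        alleles: set[str] = set()
        for call in self.calls[:, j]:
            if call is not None:
                alleles.update(call)
        return sorted(alleles)

    def all_marker_alleles(self) -> dict[str, list[str]]:
        return {m: self.marker_alleles(m) for m in self.marker_ids}

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_accessions, n_markers) array, True where missing."""
        return np.equal(self.calls, None)

    def subset(self, accession_ids=None, marker_ids=None) -> "GenotypeMatrix":
        """Row/column subset preserving the requested order."""
        acc = list(accession_ids) if accession_ids is not None else self.accession_ids
        mk = list(marker_ids) if marker_ids is not None else self.marker_ids
        rows = [self.accession_index(a) for a in acc]
        cols = [self._marker_index[m] for m in mk]
        return GenotypeMatrix(acc, mk, self.calls[np.ix_(rows, cols)].copy())


@dataclass
class TraitSpec:
    """Descriptor for one phenotype column."""

    name: str
    kind: str  # "qualitative" | "quantitative"
    class_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("qualitative", "quantitative"):
            raise FormatError(f"trait {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "qualitative":
            if not self.class_labels:
                raise FormatError(f"qualitative trait {self.name!r} declares no classes")
            if not (3 <= len(self.class_labels) <= 12):
                warnings.warn(
                    f"qualitative trait {self.name!r} has {len(self.class_labels)} "
                    "classes (outside the usual 3-12 range)",
                    stacklevel=2,
                )


@dataclass
class PhenotypeTable:
    """Per-accession trait values: class labels, finite reals, or missing."""

    accession_ids: list[str]
    traits: list[TraitSpec]
    values: np.ndarray  # object array (n_accessions, n_traits); None = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=object)
        if self.values.shape != (len(self.accession_ids), len(self.traits)):
            raise FormatError("phenotype values shape mismatch")
        self._trait_index = {t.name: j for j, t in enumerate(self.traits)}
        self._acc_index = {a: i for i, a in enumerate(self.accession_ids)}
        for j, t in enumerate(self.traits):
            for i, v in enumerate(self.values[:, j]):
                if v is None:
                    continue
                if t.kind == "qualitative":
                    if v not in t.class_labels:
                        raise FormatError(
                            f"trait {t.name!r}, accession "
                            f"{self.accession_ids[i]!r}: undeclared class {v!r}"
                        )
                else:
                    if not isinstance(v, float) or not math.isfinite(v):
                        raise FormatError(
                            f"trait {t.name!r}, accession "
                            f"{self.accession_ids[i]!r}: non-finite value {v!r}"
                        )

    def trait(self, name: str) -> TraitSpec:
        return self.traits[self._trait_index[name]]

    def column(self, name: str, accession_ids=None) -> list:
        j = self._trait_index[name]
        if accession_ids is None:
            return list(self.values[:, j])
        return [self.values[self._acc_index[a], j] for a in accession_ids]

    def quantitative_traits(self) -> list[TraitSpec]:
        return [t for t in self.traits if t.kind == "quantitative"]

    def qualitative_traits(self) -> list[TraitSpec]:
        return [t for t in self.traits if t.kind == "qualitative"]


@dataclass
class PassportTable:
    accession_ids: list[str]
    species: dict[str, str]
    origin: dict[str, str] = field(default_factory=dict)
    source: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise FormatError("duplicate accession id in passport table")
        for a in self.accession_ids:
            if not self.species.get(a):
                raise FormatError(f"passport accession {a!r} has empty species label")


@dataclass
class Collection:
    """A genotyped collection with optional phenotypes, passport, and a
    panel of hold-out markers kept apart from everything used in selection."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable | None = None
    passport: PassportTable | None = None
    holdout_genotypes: GenotypeMatrix | None = None

    def __post_init__(self) -> None:
        known = set(self.genotypes.accession_ids)
        for label, tbl in (("phenotype", self.phenotypes), ("passport", self.passport)):
            if tbl is None:
                continue
            orphans = [a for a in tbl.accession_ids if a not in known]
            if orphans:
                raise FormatError(
                    f"{label} table lists accessions absent from genotypes: {orphans}"
                )
        if self.holdout_genotypes is not None:
            overlap = set(self.holdout_genotypes.marker_ids) & set(self.genotypes.marker_ids)
            if overlap:
                raise FormatError(f"hold-out markers overlap the main panel: {sorted(overlap)}")

    @property
    def accession_ids(self) -> list[str]:
        return self.genotypes.accession_ids

    def subset(self, accession_ids) -> "Collection":
        acc = list(accession_ids)
        phen = None
        if self.phenotypes is not None:
            keep = [a for a in acc if a in self.phenotypes._acc_index]
            rows = [self.phenotypes._acc_index[a] for a in keep]
            phen = PhenotypeTable(keep, self.phenotypes.traits, self.phenotypes.values[rows])
        pp = None
        if self.passport is not None:
            keep = [a for a in acc if a in self.passport.species]
            pp = PassportTable(
                keep,
                {a: self.passport.species[a] for a in keep},
                {a: self.passport.origin[a] for a in keep if a in self.passport.origin},
                {a: self.passport.source[a] for a in keep if a in self.passport.source},
            )
        ho = None
        if self.holdout_genotypes is not None:
            ho = self.holdout_genotypes.subset(accession_ids=acc)
        return Collection(self.genotypes.subset(accession_ids=acc), phen, pp, ho)


# ---------------------------------------------------------------------------
# readers / writers


def _parse_call(cell: str, where: str) -> tuple[str, str] | None:
    cell = cell.strip()
    if cell in _MISSING_TOKENS:
        return MISSING
    parts = cell.split("/")
    if len(parts) != 2 or not all(parts):
        raise FormatError(f"non-diploid call {cell!r} at {where}")
    if "." in parts:
        return MISSING
    return normalize_call(parts[0], parts[1])


def read_genotypes(path, dialect: str = "matrix-csv") -> GenotypeMatrix:
    """Read a genotype matrix from matrix-csv or VCF.

    matrix-csv: header row of marker ids with first cell ``accession``,
    one row per accession, cells ``A/A`` / ``A/B`` / ``./.``.  The VCF
    dialect reads diploid GT fields; REF maps to allele ``R``, the i-th
    ALT to ``A`` (``A2``, ``A3``, ... beyond the first), and the marker id
    is ``contig:pos`` treated as an opaque label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if dialect == "matrix-csv":
        return _read_matrix_csv(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_matrix_csv(path: Path) -> GenotypeMatrix:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if not header or header[0].strip().lower() != "accession":
            raise FormatError(f"{path}: first header cell must be 'accession'")
        marker_ids = [h.strip() for h in header[1:]]
        accession_ids: list[str] = []
        rows: list[list] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(marker_ids) + 1:
                raise FormatError(f"{path}:{lineno}: expected {len(marker_ids) + 1} cells")
            acc = row[0].strip()
            accession_ids.append(acc)
            rows.append(
                [
                    _parse_call(cell, f"{path}:{lineno} marker {marker_ids[j]}")
                    for j, cell in enumerate(row[1:])
                ]
            )
    calls = np.empty((len(accession_ids), len(marker_ids)), dtype=object)
    for i, r in enumerate(rows):
        calls[i] = r
    return GenotypeMatrix(accession_ids, marker_ids, calls)


def _read_vcf(path: Path) -> GenotypeMatrix:
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF import requires pysam") from exc

    def allele_label(idx: int) -> str:
        if idx == 0:
            return "R"
        return "A" if idx == 1 else f"A{idx}"

    with pysam.VariantFile(str(path)) as vf:
        accession_ids = list(vf.header.samples)
        marker_ids: list[str] = []
        columns: list[list] = []
        for rec in vf:
            mid = f"{rec.chrom}:{rec.pos}"
            marker_ids.append(mid)
            col = []
            for sample in accession_ids:
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    col.append(MISSING)
                    continue
                if len(gt) != 2:
                    raise FormatError(
                        f"non-diploid GT for sample {sample} at {mid}: {gt}"
                    )
                col.append(normalize_call(allele_label(gt[0]), allele_label(gt[1])))
            columns.append(col)
    calls = np.empty((len(accession_ids), len(marker_ids)), dtype=object)
    for j, col in enumerate(columns):
        calls[:, j] = col
    return GenotypeMatrix(accession_ids, marker_ids, calls)


def write_genotypes(m: GenotypeMatrix, path) -> None:
    """Write matrix-csv with input row/column order; missing as ``./.``."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["accession"] + list(m.marker_ids))
        for i, acc in enumerate(m.accession_ids):
            row = [acc]
            for call in m.calls[i]:
                row.append("./." if call is None else f"{call[0]}/{call[1]}")
            writer.writerow(row)


def read_trait_schema(path) -> list[TraitSpec]:
    """Trait schema JSON: list of {name, kind, classes?} objects."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return [
        TraitSpec(d["name"], d["kind"], d.get("classes") or d.get("class_labels"))
        for d in raw
    ]


def write_trait_schema(traits: list[TraitSpec], path) -> None:
    payload = [
        {"name": t.name, "kind": t.kind, **({"classes": t.class_labels} if t.class_labels else {})}
        for t in traits
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def read_phenotypes(path, schema: list[TraitSpec]) -> PhenotypeTable:
    """Read a phenotype CSV against a declared trait schema.

    Every non-id column must be declared in ``schema``; qualitative cells
    are checked against the declared classes, quantitative cells parsed
    as reals.  Empty cells and ``NA`` are missing.
    """
    by_name = {t.name: t for t in schema}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if not header or header[0].strip().lower() != "accession":
            raise FormatError(f"{path}: first header cell must be 'accession'")
        names = [h.strip() for h in header[1:]]
        undeclared = [n for n in names if n not in by_name]
        if undeclared:
            raise FormatError(f"{path}: traits not declared in schema: {undeclared}")
        traits = [by_name[n] for n in names]
        accession_ids: list[str] = []
        rows: list[list] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            acc = row[0].strip()
            accession_ids.append(acc)
            vals: list = []
            for t, cell in zip(traits, row[1:]):
                cell = cell.strip()
                if cell in ("", "NA", "na", "."):
                    vals.append(MISSING)
                elif t.kind == "qualitative":
                    if cell not in t.class_labels:
                        raise FormatError(
                            f"{path}:{lineno}: trait {t.name!r}, accession {acc!r}: "
                            f"undeclared class {cell!r}"
                        )
                    vals.append(cell)
                else:
                    try:
                        vals.append(float(cell))
                    except ValueError:
                        raise FormatError(
                            f"{path}:{lineno}: trait {t.name!r}, accession {acc!r}: "
                            f"cannot parse {cell!r} as a number"
                        ) from None
            rows.append(vals)
    values = np.empty((len(accession_ids), len(traits)), dtype=object)
    for i, r in enumerate(rows):
        values[i] = r
    return PhenotypeTable(accession_ids, traits, values)


def write_phenotypes(p: PhenotypeTable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["accession"] + [t.name for t in p.traits])
        for i, acc in enumerate(p.accession_ids):
            row = [acc]
            for v in p.values[i]:
                row.append("" if v is None else (repr(v) if isinstance(v, float) else v))
            writer.writerow(row)


def read_passport(path) -> PassportTable:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        ids, species, origin, source = [], {}, {}, {}
        for row in reader:
            acc = row["accession"].strip()
            ids.append(acc)
            species[acc] = row.get("species", "").strip()
            origin[acc] = row.get("origin", "UNKNOWN").strip() or "UNKNOWN"
            source[acc] = row.get("source", "").strip()
    return PassportTable(ids, species, origin, source)


def write_passport(p: PassportTable, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["accession", "species", "origin", "source"])
        for acc in p.accession_ids:
            writer.writerow(
                [acc, p.species[acc], p.origin.get(acc, "UNKNOWN"), p.source.get(acc, "")]
            )


def merge_collection(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable | None = None,
    passport: PassportTable | None = None,
    holdout_genotypes: GenotypeMatrix | None = None,
) -> Collection:
    """Assemble a Collection, rejecting phenotype/passport orphans."""
    if phenotypes is not None and not phenotypes.accession_ids:
        phenotypes = None
    return Collection(genotypes, phenotypes, passport, holdout_genotypes)
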
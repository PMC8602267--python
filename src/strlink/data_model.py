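"""Domain types and I/O for multiallelic genotype data.

The pipeline works on a small panel of markers around a functional SNP:
microsatellites (STRs) whose alleles are named relative to the reference
repeat count ("R" = reference, "+n"/"-n" = n repeats more/fewer), and SNPs
whose alleles are bases.  Genotypes are unphased diploid calls stored as
unordered allele pairs; all downstream statistics (gene counting, EM
haplotype estimation, LD, odds ratios) consume this representation.

File formats are plain TSV:

``panel.tsv``
    columns ``name, chrom, pos, kind, repeat_unit, ref_repeat_count``;
    one row per marker, positions 1-based (GRCh38).

``genotypes.tsv``
    columns ``sample_id, population, group`` (group optional) then
    ``<marker>_A1`` / ``<marker>_A2`` per marker; missing calls are ".".
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("strlink")

MISSING = "."

# Unicode variants of the minus sign seen in published tables are
# normalised to ASCII hyphen-minus on input.
_MINUS_VARIANTS = {"−", "–", "—"}


class MarkerKind(str, Enum):
    STR = "STR"
    SNP = "SNP"


class StrlinkError(Exception):
    """Base class for all package errors."""


class ValidationError(StrlinkError):
    pass


class ParseError(StrlinkError):
    pass


class EmptyGroupError(StrlinkError):
    pass


# ---------------------------------------------------------------------------
# Allele labels
# ---------------------------------------------------------------------------

def normalise_label(raw: str) -> str:
    """Strip whitespace and map unicode minus variants to '-'."""
    s = str(raw).strip()
    for ch in _MINUS_VARIANTS:
        s = s.replace(ch, "-")
    return s.replace(" ", "")


def parse_str_offset(label: str) -> int:
    """Parse an STR allele label into its repeat offset.

    "R" -> 0, "+n" -> n, "-n" -> -n.
    """
    s = normalise_label(label)
    if s == "R":
        return 0
    if s and s[0] in "+-":
        try:
            value = int(s)
        except ValueError:
            raise ParseError(f"invalid STR allele label {label!r}")
        if value == 0:
            raise ParseError(f"offset 0 must be written 'R', got {label!r}")
        return value
    # bare integers are accepted on input (published tables print "2"
    # for "+2") but always formatted back with an explicit sign
    try:
        value = int(s)
    except ValueError:
        raise ParseError(f"invalid STR allele label {label!r}")
    if value == 0:
        return 0
    return value


def format_str_offset(offset: int) -> str:
    if offset == 0:
        return "R"
    return f"+{offset}" if offset > 0 else str(offset)


_SNP_BASES = frozenset("ACGT")


@functools.total_ordering
@dataclass(frozen=True)
class AlleleLabel:
    """A marker allele: repeat-offset symbol for STRs, base for SNPs.

    STR labels order by offset (so "-4" < "R" < "+2"); SNP labels order
    lexicographically.  ``raw`` is always the canonical spelling.
    """

    raw: str
    offset: Optional[int] = None

    @classmethod
    def parse(cls, label: str, kind: MarkerKind) -> "AlleleLabel":
        s = normalise_label(label)
        if kind is MarkerKind.STR:
            off = parse_str_offset(s)
            return cls(raw=format_str_offset(off), offset=off)
        base = s.upper()
        if base not in _SNP_BASES:
            raise ParseError(f"invalid SNP allele {label!r} (expected a base)")
        return cls(raw=base, offset=None)

    @property
    def is_str(self) -> bool:
        return self.offset is not None

    def _key(self):
        if self.offset is not None:
            return (0, self.offset, "")
        return (1, 0, self.raw)

    def __lt__(self, other: "AlleleLabel") -> bool:
        if not isinstance(other, AlleleLabel):
            return NotImplemented
        return self._key() < other._key()

    def __str__(self) -> str:
        return self.raw


def sort_alleles(labels: Iterable[str], kind: MarkerKind) -> list[str]:
    """Canonical ordering of raw labels: by offset for STRs, lexicographic for SNPs."""
    return [a.raw for a in sorted(AlleleLabel.parse(l, kind) for l in labels)]


# ---------------------------------------------------------------------------
# Marker panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerDef:
    name: str
    chrom: str
    pos: int
    kind: MarkerKind
    repeat_unit: Optional[str] = None
    ref_repeat_count: Optional[int] = None

    def __post_init__(self):
        if self.pos <= 0:
            raise ValidationError(f"marker {self.name}: pos must be positive")
        if self.kind is MarkerKind.STR:
            if not self.repeat_unit:
                raise ValidationError(f"STR marker {self.name} needs a repeat_unit")
        else:
            if self.repeat_unit or self.ref_repeat_count:
                raise ValidationError(
                    f"SNP marker {self.name} must not carry repeat_unit/ref_repeat_count"
                )

    def parse_allele(self, label: str) -> AlleleLabel:
        return AlleleLabel.parse(label, self.kind)


def validate_panel(markers: Sequence[MarkerDef]) -> list[MarkerDef]:
    """Check name uniqueness and return the panel sorted by (chrom, pos, name)."""
    seen: set[str] = set()
    for m in markers:
        if m.name in seen:
            raise ValidationError(f"duplicate marker name {m.name!r} in panel")
        seen.add(m.name)
    return sorted(markers, key=lambda m: (m.chrom, m.pos, m.name))


def read_marker_panel(path) -> list[MarkerDef]:
    """Read a tab-separated marker panel file into a validated, sorted panel."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"name", "chrom", "pos", "kind"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ParseError(f"panel file missing columns: {sorted(missing_cols)}")
    markers: list[MarkerDef] = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            pos = int(row["pos"])
        except ValueError:
            raise ParseError(f"non-integer pos {row['pos']!r} at line {line_no}")
        kind_raw = row["kind"].strip().upper()
        try:
            kind = MarkerKind(kind_raw)
        except ValueError:
            raise ParseError(f"unknown marker kind {row['kind']!r} at line {line_no}")
        repeat_unit = row.get("repeat_unit", "") or None
        ref_rc = row.get("ref_repeat_count", "") or None
        markers.append(
            MarkerDef(
                name=row["name"].strip(),
                chrom=row["chrom"].strip(),
                pos=pos,
                kind=kind,
                repeat_unit=repeat_unit if kind is MarkerKind.STR else None,
                ref_repeat_count=int(ref_rc) if (ref_rc and kind is MarkerKind.STR) else None,
            )
        )
    if not markers:
        logger.warning("panel file %s contains no markers", path)
    return validate_panel(markers)


def write_marker_panel(panel: Sequence[MarkerDef], path) -> None:
    rows = [
        {
            "name": m.name,
            "chrom": m.chrom,
            "pos": m.pos,
            "kind": m.kind.value,
            "repeat_unit": m.repeat_unit or "",
            "ref_repeat_count": m.ref_repeat_count or "",
        }
        for m in panel
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype table
# ---------------------------------------------------------------------------

Call = Optional[tuple[str, str]]  # canonical (sorted) unordered allele pair


@dataclass
class GenotypeTable:
    """Unphased diploid genotypes for a sample set over a marker panel.

    ``calls[marker][i]`` is the i-th sample's unordered allele pair at
    ``marker``, stored canonically (sorted by allele ordering), or ``None``
    for a missing call.  Half-calls are rejected on construction.
    """

    panel: list[MarkerDef]
    samples: pd.DataFrame  # columns: sample_id, population, group
    calls: dict[str, list[Call]]

    def __post_init__(self):
        n = len(self.samples)
        self.marker_map = {m.name: m for m in self.panel}
        for name, col in self.calls.items():
            if name not in self.marker_map:
                raise ValidationError(f"calls for unknown marker {name!r}")
            if len(col) != n:
                raise ValidationError(f"marker {name}: {len(col)} calls for {n} samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.panel if m.name in self.calls]

    def marker(self, name: str) -> MarkerDef:
        try:
            return self.marker_map[name]
        except KeyError:
            raise ValidationError(f"marker {name!r} not in panel")

    def group_mask(self, group: str) -> pd.Series:
        return self.samples["group"] == group

    def with_groups(self, groups: Sequence[Optional[str]]) -> "GenotypeTable":
        samples = self.samples.copy()
        samples["group"] = list(groups)
        return GenotypeTable(panel=self.panel, samples=samples, calls=self.calls)

    def complete_case_index(self, loci: Sequence[str]) -> list[int]:
        """Indices of samples with no missing call at any of ``loci``."""
        return [
            i
            for i in range(self.n_samples)
            if all(self.calls[l][i] is not None for l in loci)
        ]

    def subset(self, indices: Sequence[int]) -> "GenotypeTable":
        samples = self.samples.iloc[list(indices)].reset_index(drop=True)
        calls = {m: [col[i] for i in indices] for m, col in self.calls.items()}
        return GenotypeTable(panel=self.panel, samples=samples, calls=calls)

    def merge_alleles(self, merge_map: Mapping[str, Mapping[str, str]]) -> "GenotypeTable":
        """Relabel alleles per marker (e.g. merging indistinguishable calls).

        ``merge_map`` maps marker name -> {old_label: new_label}.  Pairs are
        re-canonicalised after relabelling.
        """
        calls = dict(self.calls)
        for name, mapping in merge_map.items():
            marker = self.marker(name)
            norm = {
                normalise_label(k): marker.parse_allele(v).raw for k, v in mapping.items()
            }
            new_col: list[Call] = []
            for call in self.calls[name]:
                if call is None:
                    new_col.append(None)
                    continue
                relabelled = [norm.get(a, a) for a in call]
                new_col.append(canonical_pair(relabelled[0], relabelled[1], marker.kind))
            calls[name] = new_col
        return GenotypeTable(panel=self.panel, samples=self.samples.copy(), calls=calls)


def canonical_pair(a: str, b: str, kind: MarkerKind) -> tuple[str, str]:
    """Canonical unordered pair: parsed, validated, sorted by allele order."""
    la, lb = AlleleLabel.parse(a, kind), AlleleLabel.parse(b, kind)
    if lb < la:
        la, lb = lb, la
    return (la.raw, lb.raw)


def read_genotypes(path, panel: Sequence[MarkerDef]) -> GenotypeTable:
    """Read a genotype TSV against a marker panel.

    Every panel marker with an ``<name>_A1`` column must also have
    ``<name>_A2`` (and vice versa); a call is missing iff both columns are
    ".".  Allele labels are validated under the marker's kind.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ParseError("genotype file must have a sample_id column")
    samples = pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "population": df.get("population", pd.Series([""] * len(df))),
            "group": df.get("group", pd.Series([None] * len(df))),
        }
    )
    samples["group"] = samples["group"].where(
        samples["group"].notna() & (samples["group"] != ""), None
    )
    calls: dict[str, list[Call]] = {}
    for m in panel:
        c1, c2 = f"{m.name}_A1", f"{m.name}_A2"
        has1, has2 = c1 in df.columns, c2 in df.columns
        if has1 != has2:
            raise ParseError(f"marker {m.name}: found only one of {c1}/{c2} (half-call)")
        if not has1:
            continue
        col: list[Call] = []
        for idx, (a, b) in enumerate(zip(df[c1], df[c2])):
            a, b = normalise_label(a), normalise_label(b)
            a_missing, b_missing = a == MISSING, b == MISSING
            if a_missing != b_missing:
                raise ParseError(
                    f"half-call at sample {df['sample_id'][idx]!r}, marker {m.name}"
                )
            if a_missing:
                col.append(None)
            else:
                try:
                    col.append(canonical_pair(a, b, m.kind))
                except ParseError as e:
                    raise ParseError(
                        f"sample {df['sample_id'][idx]!r}, marker {m.name}: {e}"
                    ) from e
        calls[m.name] = col
    return GenotypeTable(panel=validate_panel(list(panel)), samples=samples, calls=calls)


def write_genotypes(gt: GenotypeTable, path) -> None:
    """Write a GenotypeTable back to TSV (round-trips with read_genotypes)."""
    out = gt.samples.copy()
    out["group"] = out["group"].fillna("") if out["group"].notna().any() else ""
    for name in gt.marker_names:
        col = gt.calls[name]
        out[f"{name}_A1"] = [c[0] if c else MISSING for c in col]
        out[f"{name}_A2"] = [c[1] if c else MISSING for c in col]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable2xK:
    """2 x K allele (or haplotype) count table for two groups."""

    row_labels: tuple[str, str]
    col_labels: list[str]
    counts: np.ndarray  # shape (2, K), non-negative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, len(self.col_labels)):
            raise ValidationError("contingency counts shape mismatch")
        if (self.counts < 0).any():
            raise ValidationError("negative counts in contingency table")

    @property
    def row_totals(self):
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def count_alleles(
    gt: GenotypeTable, marker: str, groups: tuple[str, str]
) -> ContingencyTable2xK:
    """Gene-counting 2xK table of allele counts for two phenotype groups.

    Samples missing at ``marker`` are dropped from their group; every
    retained sample contributes exactly two chromosomes to its row.
    """
    m = gt.marker(marker)
    col = gt.calls[marker]
    tallies: list[dict[str, int]] = []
    for g in groups:
        tally: dict[str, int] = {}
        idx = gt.samples.index[gt.group_mask(g)]
        for i in idx:
            call = col[i]
            if call is None:
                continue
            for a in call:
                tally[a] = tally.get(a, 0) + 1
        if not tally:
            raise EmptyGroupError(
                f"group {g!r} has no non-missing samples at marker {marker}"
            )
        tallies.append(tally)
    alleles = sort_alleles(set(tallies[0]) | set(tallies[1]), m.kind)
    counts = np.array([[t.get(a, 0) for a in alleles] for t in tallies], dtype=np.int64)
    return ContingencyTable2xK(row_labels=tuple(groups), col_labels=alleles, counts=counts)
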
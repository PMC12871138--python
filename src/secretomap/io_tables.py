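"""Readers, writers and domain containers for every table the pipeline touches.

All on-disk formats are plain TSV (GMT for term maps).  Missing reporter
intensities are empty cells on disk and ``NaN`` in memory — never zero,
because zero is a legal measured value and downstream filters must
distinguish "not quantified" from "absent".

Protein IDs are opaque, case-sensitive strings.  Gene-symbol mapping, if
needed, is the caller's responsibility via the annotation catalog.
"""

from __future__ import annotations

import dataclasses
import io
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import SchemaError, ValidationError

GENOTYPES = ("cre_pos", "cre_neg")

#: Common concentration unit for the plasma catalog (smallest unit in use).
CONCENTRATION_UNIT = "pmol/mL"

_UNIT_TO_PMOL_ML = {"pmol/mL": 1.0, "nmol/mL": 1000.0}

#: Fixed float rendering so reruns are byte-identical.
FLOAT_FORMAT = "%.6g"

DESIGN_COLUMNS = ("channel_id", "genotype", "condition", "tissue", "replicate", "plex_id")


@dataclass(frozen=True)
class ChannelDesign:
    """One TMT channel of a multiplexed experiment.

    ``genotype`` separates ligase-expressing (``cre_pos``) channels from
    the matched Cre-negative background controls.
    """

    channel_id: str
    genotype: str
    condition: str
    tissue: str
    replicate: int
    plex_id: str

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ValidationError(
                f"channel {self.channel_id!r}: genotype must be one of {GENOTYPES}, "
                f"got {self.genotype!r}"
            )
        if self.replicate < 1:
            raise ValidationError(f"channel {self.channel_id!r}: replicate must be >= 1")


class QuantExperiment:
    """Protein x channel reporter-intensity matrix plus its channel design.

    Parameters
    ----------
    intensities
        DataFrame indexed by protein ID with one column per channel ID.
        Values are non-negative reporter intensities; ``NaN`` marks a
        missing (unquantified) entry.
    design
        One :class:`ChannelDesign` per intensity column, same order.
    """

    def __init__(self, intensities: pd.DataFrame, design: Sequence[ChannelDesign]):
        design = list(design)
        if list(intensities.columns) != [c.channel_id for c in design]:
            raise ValidationError("intensity columns and design channel_ids must match in order")
        if intensities.index.duplicated().any():
            dups = intensities.index[intensities.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein IDs: {dups[:5]}")
        vals = intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("reporter intensities must be >= 0 where present")
        for plex in {c.plex_id for c in design}:
            chans = [c for c in design if c.plex_id == plex]
            ids = [c.channel_id for c in chans]
            if len(ids) != len(set(ids)):
                raise ValidationError(f"plex {plex!r}: duplicate channel_id")
            genos = {c.genotype for c in chans}
            if not {"cre_pos", "cre_neg"} <= genos:
                raise ValidationError(
                    f"plex {plex!r} must contain at least one cre_pos and one cre_neg channel"
                )
        self.intensities = intensities.astype(float)
        self.design = design

    # -- convenience accessors -------------------------------------------------

    @property
    def proteins(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def n_proteins(self) -> int:
        return len(self.intensities.index)

    def design_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(c) for c in self.design], columns=DESIGN_COLUMNS)

    def channel_ids(self, genotype: str | None = None, condition: str | None = None,
                    plex_id: str | None = None) -> list[str]:
        """Channel IDs matching the given design fields (None = any)."""
        out = []
        for c in self.design:
            if genotype is not None and c.genotype != genotype:
                continue
            if condition is not None and c.condition != condition:
                continue
            if plex_id is not None and c.plex_id != plex_id:
                continue
            out.append(c.channel_id)
        return out

    def plex_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.design:
            seen.setdefault(c.plex_id, None)
        return list(seen)

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.design:
            seen.setdefault(c.condition, None)
        return list(seen)

    def subset_plex(self, plex_id: str) -> "QuantExperiment":
        chans = [c for c in self.design if c.plex_id == plex_id]
        if not chans:
            raise ValidationError(f"unknown plex_id {plex_id!r}")
        return QuantExperiment(self.intensities[[c.channel_id for c in chans]], chans)

    def __eq__(self, other) -> bool:
        return (isinstance(other, QuantExperiment)
                and self.design == other.design
                and self.intensities.equals(other.intensities))


@dataclass(frozen=True)
class TermMap:
    """One annotation term (e.g. a GO term) and its member proteins."""

    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"term {self.term_id!r}: members must be non-empty")


class AnnotationCatalog:
    """Per-protein localization and secretion annotations.

    Backed by a DataFrame indexed by protein ID with columns:

    - ``cc_terms`` : frozenset of cellular-component labels
    - ``signal_peptide``, ``ups_predicted``, ``transmembrane`` : bool
    - ``tissue_enriched`` : str or None
    - ``concentration_pmol_ml`` : float (NaN when unknown), common unit pmol/mL

    Flags are independent: a protein may carry a signal peptide and be
    transmembrane; mutually exclusive classes are derived downstream.
    """

    COLUMNS = ("cc_terms", "signal_peptide", "ups_predicted", "transmembrane",
               "tissue_enriched", "concentration_pmol_ml")

    def __init__(self, table: pd.DataFrame):
        if table.index.duplicated().any():
            dups = table.index[table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein in annotation catalog: {dups[:5]}")
        for col in self.COLUMNS:
            if col not in table.columns:
                raise SchemaError(f"annotation catalog missing column {col!r}")
        conc = table["concentration_pmol_ml"]
        if (conc.dropna() <= 0).any():
            raise ValidationError("plasma concentration must be > 0 when present")
        self.table = table

    def __contains__(self, protein: str) -> bool:
        return protein in self.table.index

    def __len__(self) -> int:
        return len(self.table)

    @property
    def proteins(self) -> list[str]:
        return list(self.table.index)

    def cc_terms(self, protein: str) -> frozenset[str]:
        if protein not in self.table.index:
            return frozenset()
        return self.table.at[protein, "cc_terms"]

    def flag(self, protein: str, name: str) -> bool:
        if protein not in self.table.index:
            return False
        return bool(self.table.at[protein, name])

    def concentration(self, protein: str) -> float | None:
        """Absolute plasma concentration in pmol/mL, or None if unknown."""
        if protein not in self.table.index:
            return None
        v = self.table.at[protein, "concentration_pmol_ml"]
        return None if pd.isna(v) else float(v)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_design_table(path: str | Path) -> list[ChannelDesign]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"design table {path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        try:
            rep = int(row["replicate"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"design table {path}: replicate {row['replicate']!r} is not an integer"
            ) from None
        out.append(ChannelDesign(channel_id=str(row["channel_id"]), genotype=str(row["genotype"]),
                                 condition=str(row["condition"]), tissue=str(row["tissue"]),
                                 replicate=rep, plex_id=str(row["plex_id"])))
    return out


def read_quant_table(path: str | Path, design_path: str | Path) -> QuantExperiment:
    """Read a protein x channel TSV and its channel-design TSV.

    The quant file has a protein-ID column (first column) and one column
    per channel.  Empty or unparseable intensity cells become missing,
    not zero.  Every quant column must have a design row; duplicate
    protein rows are an error.
    """
    design = read_design_table(design_path)
    by_id = {c.channel_id: c for c in design}
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise SchemaError(f"quant table {path}: need a protein column plus >=1 channel column")
    protein_col = raw.columns[0]
    channel_cols = list(raw.columns[1:])
    unknown = [c for c in channel_cols if c not in by_id]
    if unknown:
        raise SchemaError(
            f"quant table {path}: column(s) {unknown} have no row in the design table"
        )
    proteins = raw[protein_col].astype(str)
    if proteins.duplicated().any():
        dups = proteins[proteins.duplicated()].unique().tolist()
        raise ValidationError(f"quant table {path}: duplicate protein IDs {dups[:5]}")
    mat = raw[channel_cols].apply(pd.to_numeric, errors="coerce")
    if (mat.to_numpy() < 0).any():
        raise ValidationError(f"quant table {path}: negative intensity")
    mat.index = pd.Index(proteins, name="protein")
    ordered = [by_id[c] for c in channel_cols]
    return QuantExperiment(mat, ordered)


_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n", "", "nan"}


def _parse_bool(value, *, context: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"{context}: cannot parse boolean {value!r}")


def read_annotation_catalog(path: str | Path) -> AnnotationCatalog:
    """Read a per-protein annotation TSV.

    Expected columns: ``protein``, ``cc_terms`` (semicolon-delimited),
    ``signal_peptide``, ``ups_predicted``, ``transmembrane``, and the
    optional ``tissue_enriched``, ``concentration``, ``concentration_unit``
    (pmol/mL or nmol/mL; stored internally in pmol/mL).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ("protein", "cc_terms", "signal_peptide", "ups_predicted", "transmembrane")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"annotation catalog {path}: missing columns {missing}")

    records = {}
    for i, row in df.iterrows():
        pid = str(row["protein"])
        if pid in records:
            raise ValidationError(f"annotation catalog {path}: duplicate protein {pid!r}")
        cc_raw = row["cc_terms"]
        cc = frozenset(t.strip() for t in str(cc_raw).split(";") if t.strip()) \
            if pd.notna(cc_raw) else frozenset()
        conc = np.nan
        if "concentration" in df.columns and pd.notna(row["concentration"]) \
                and str(row["concentration"]).strip() != "":
            try:
                value = float(row["concentration"])
            except ValueError:
                raise ValidationError(
                    f"annotation catalog {path}: bad concentration {row['concentration']!r} "
                    f"for {pid}") from None
            unit = str(row.get("concentration_unit", CONCENTRATION_UNIT)).strip()
            if unit not in _UNIT_TO_PMOL_ML:
                raise ValidationError(
                    f"annotation catalog {path}: unknown concentration unit {unit!r} for {pid} "
                    f"(known: {sorted(_UNIT_TO_PMOL_ML)})")
            if value <= 0:
                raise ValidationError(
                    f"annotation catalog {path}: concentration must be > 0, got {value} for {pid}")
            conc = value * _UNIT_TO_PMOL_ML[unit]
        tissue = None
        if "tissue_enriched" in df.columns and pd.notna(row["tissue_enriched"]) \
                and str(row["tissue_enriched"]).strip() != "":
            tissue = str(row["tissue_enriched"]).strip()
        records[pid] = {
            "cc_terms": cc,
            "signal_peptide": _parse_bool(row["signal_peptide"], context=f"{pid} signal_peptide"),
            "ups_predicted": _parse_bool(row["ups_predicted"], context=f"{pid} ups_predicted"),
            "transmembrane": _parse_bool(row["transmembrane"], context=f"{pid} transmembrane"),
            "tissue_enriched": tissue,
            "concentration_pmol_ml": conc,
        }
    table = pd.DataFrame.from_dict(records, orient="index", columns=list(AnnotationCatalog.COLUMNS))
    table.index.name = "protein"
    return AnnotationCatalog(table)


def read_gmt(path: str | Path) -> list[TermMap]:
    """Read a GMT file: per line, term id, description, then member IDs.

    Duplicate members within a line are deduplicated (set semantics).
    A line with fewer than three tab-separated fields is a parse error.
    """
    terms: list[TermMap] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            term_id, term_name = fields[0], fields[1]
            if term_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate term_id {term_id!r}")
            seen.add(term_id)
            members = frozenset(m for m in fields[2:] if m.strip())
            terms.append(TermMap(term_id=term_id, term_name=term_name, members=members))
    return terms


def write_gmt(terms: Iterable[TermMap], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.term_name, *sorted(t.members)]) + "\n")


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_result_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a pipeline result table as deterministic TSV.

    Rows are sorted by protein ID (then contrast, where present), columns
    keep their given order, floats are rendered at fixed precision, and
    the missing marker is the empty cell — so identical inputs always
    produce byte-identical files.
    """
    df = table.copy()
    sort_cols = [c for c in ("protein", "contrast") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep="",
              lineterminator="\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def write_quant_table(q: QuantExperiment, quant_path: str | Path,
                      design_path: str | Path) -> None:
    """Write a QuantExperiment back to the quant + design TSV pair."""
    mat = q.intensities.reset_index()
    mat = mat.rename(columns={mat.columns[0]: "protein"})
    buf = io.StringIO()
    mat.to_csv(buf, sep="\t", index=False, float_format="%.10g", na_rep="",
               lineterminator="\n")
    Path(quant_path).write_text(buf.getvalue(), encoding="utf-8")
    buf = io.StringIO()
    q.design_frame().to_csv(buf, sep="\t", index=False, lineterminator="\n")
    Path(design_path).write_text(buf.getvalue(), encoding="utf-8")


def write_annotation_catalog(catalog: AnnotationCatalog, path: str | Path) -> None:
    rows = []
    for pid in catalog.proteins:
        rec = catalog.table.loc[pid]
        conc = rec["concentration_pmol_ml"]
        rows.append({
            "protein": pid,
            "cc_terms": ";".join(sorted(rec["cc_terms"])),
            "signal_peptide": rec["signal_peptide"],
            "ups_predicted": rec["ups_predicted"],
            "transmembrane": rec["transmembrane"],
            "tissue_enriched": rec["tissue_enriched"] if rec["tissue_enriched"] else "",
            "concentration": "" if pd.isna(conc) else conc,
            "concentration_unit": "" if pd.isna(conc) else CONCENTRATION_UNIT,
        })
    df = pd.DataFrame(rows).sort_values("protein", kind="mergesort")
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.10g", lineterminator="\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
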
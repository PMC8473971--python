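"""Readers and writers for TE/gene annotations, homolog tables and call matrices.

All coordinates inside the package are GFF3-style 1-based inclusive.
BED files are converted to/from 0-based half-open at the I/O boundary
only, so the dominant input format (GFF3) is never double-converted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

#: Recognised TE orders (top-level categories by replication mechanism).
ORDERS = ("LTR", "TIR", "Helitron")

#: Call-matrix cell labels. "missing" means no data, "ambiguous" means the
#: classifier probability fell between the absent and present thresholds.
PRESENT, ABSENT, AMBIGUOUS, MISSING = "present", "absent", "ambiguous", "missing"
LABELS = (PRESENT, ABSENT, AMBIGUOUS, MISSING)

#: Default mapping from GFF3 feature type (Sequence Ontology term) to TE
#: order. Annotation dialects differ, so callers may override it.
DEFAULT_TYPE_TO_ORDER: Mapping[str, str] = {
    "LTR_retrotransposon": "LTR",
    "solo_LTR": "LTR",
    "terminal_inverted_repeat_element": "TIR",
    "TIR_transposon": "TIR",
    "helitron": "Helitron",
    "Helitron": "Helitron",
}


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass
class TEAnnotation:
    """One annotated transposable element in one reference assembly.

    ``ltr_similarity`` is the percent identity of the element's two long
    terminal repeats (a proxy for insertion age: higher = younger) and is
    meaningful only for the LTR order. ``nested_in`` names the immediate
    outer element whose interval fully contains this one.
    """

    te_id: str
    assembly: str
    chrom: str
    start: int
    end: int
    order: str
    superfamily: str = ""
    family: str = ""
    ltr_similarity: float | None = None
    nested_in: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"TE {self.te_id}: start {self.start} > end {self.end}"
            )
        if self.order not in ORDERS:
            raise AnnotationError(f"TE {self.te_id}: unknown order {self.order!r}")
        if self.ltr_similarity is not None:
            if self.order != "LTR":
                raise AnnotationError(
                    f"TE {self.te_id}: ltr_similarity set on non-LTR order"
                )
            if not 0.0 <= self.ltr_similarity <= 100.0:
                raise AnnotationError(
                    f"TE {self.te_id}: ltr_similarity {self.ltr_similarity} "
                    "outside [0, 100]"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, other: "TEAnnotation") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class GeneModel:
    """A gene with the exon/UTR structure of one representative transcript."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exon [{s},{e}] outside gene bounds"
                )
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise AnnotationError(
                    f"gene {self.gene_id}: overlapping exons [{s1},{e1}], [{s2},{e2}]"
                )

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, 1-based inclusive."""
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 - e1 > 1:
                out.append((e1 + 1, s2 - 1))
        return out


@dataclass
class HomologGroup:
    """Homologous copies of one TE across assemblies, collapsed to one id."""

    nonredundant_id: str
    members: list[tuple[str, str]]  # (assembly, te_id)
    source_assembly: str

    def __post_init__(self) -> None:
        if not self.members:
            raise AnnotationError(
                f"group {self.nonredundant_id}: must have >= 1 member"
            )


# ---------------------------------------------------------------------------
# GFF3 readers


def _validate_gff3_lines(path: str | Path) -> None:
    # gffutils reports malformed input poorly; do a cheap column check first
    # so the error carries a line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) < 9:
                raise AnnotationError(
                    f"{path}: malformed GFF3 line {lineno}: expected 9 "
                    f"tab-separated fields"
                )


def _gff_db(path: str | Path) -> gffutils.FeatureDB:
    _validate_gff3_lines(path)
    return gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def read_te_annotations(
    path: str | Path,
    assembly: str,
    *,
    family_key: str = "fam",
    superfamily_key: str = "sup",
    similarity_key: str = "ltr_identity",
    nesting_key: str = "nested_in",
    type_to_order: Mapping[str, str] = DEFAULT_TYPE_TO_ORDER,
    resolve_nesting: str = "auto",
) -> list[TEAnnotation]:
    """Parse a TE annotation GFF3 into :class:`TEAnnotation` records.

    Attribute keys differ between annotation dialects, hence the keyword
    knobs. LTR identity values <= 1 are interpreted as fractions and
    rescaled to percent. ``resolve_nesting`` is one of:

    - ``"attribute"``: use only the ``nesting_key`` attribute;
    - ``"containment"``: recompute nesting by strict interval containment;
    - ``"auto"`` (default): use attributes when any feature carries one,
      otherwise fall back to containment;
    - ``"none"``: leave ``nested_in`` unset.
    """
    db = _gff_db(path)
    tes: list[TEAnnotation] = []
    nested_attr_seen = False
    for feat in db.all_features():
        order = type_to_order.get(feat.featuretype)
        if order is None:
            continue
        attrs = feat.attributes
        te_id = attrs.get("ID", [None])[0]
        if te_id is None:
            raise AnnotationError(
                f"{path}: feature at {feat.seqid}:{feat.start}-{feat.end} "
                "has no ID attribute"
            )
        family = attrs.get(family_key, [""])[0]
        superfamily = attrs.get(superfamily_key, [family[:3] if family else ""])[0]
        sim = None
        if order == "LTR" and similarity_key in attrs:
            sim = float(attrs[similarity_key][0])
            if sim <= 1.0:
                sim *= 100.0
            if not 0.0 <= sim <= 100.0:
                raise AnnotationError(
                    f"{path}: TE {te_id}: LTR similarity {sim} outside [0, 100]"
                )
        nested = attrs.get(nesting_key, [None])[0]
        if nested is not None:
            nested_attr_seen = True
        tes.append(
            TEAnnotation(
                te_id=te_id,
                assembly=assembly,
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                order=order,
                superfamily=superfamily,
                family=family,
                ltr_similarity=sim,
                nested_in=nested,
            )
        )
    if resolve_nesting == "containment" or (
        resolve_nesting == "auto" and not nested_attr_seen
    ):
        assign_nesting_by_containment(tes)
    elif resolve_nesting == "none":
        for te in tes:
            te.nested_in = None
    if resolve_nesting in ("attribute", "auto") and nested_attr_seen:
        _check_nesting(tes)
    return tes


def assign_nesting_by_containment(tes: Sequence[TEAnnotation]) -> None:
    """Set ``nested_in`` to the immediate strictly-containing TE, in place.

    A TE is nested in the smallest other TE whose interval contains it on
    the same chromosome; identical intervals are not nesting.
    """
    by_chrom: dict[str, list[TEAnnotation]] = {}
    for te in tes:
        by_chrom.setdefault(te.chrom, []).append(te)
    for group in by_chrom.values():
        group.sort(key=lambda t: (t.start, -t.end))
        stack: list[TEAnnotation] = []
        for te in group:
            while stack and stack[-1].end < te.end:
                stack.pop()
            parent = None
            for cand in reversed(stack):
                if (cand.start, cand.end) != (te.start, te.end):
                    parent = cand
                    break
            te.nested_in = parent.te_id if parent is not None else None
            stack.append(te)


def _check_nesting(tes: Sequence[TEAnnotation]) -> None:
    by_id = {te.te_id: te for te in tes}
    for te in tes:
        if te.nested_in is None:
            continue
        parent = by_id.get(te.nested_in)
        if parent is None:
            raise AnnotationError(
                f"TE {te.te_id}: nested_in {te.nested_in!r} not in annotation"
            )
        if not parent.contains(te):
            raise AnnotationError(
                f"TE {te.te_id}: not contained in declared outer {parent.te_id}"
            )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3.

    When a gene has several transcripts, the transcript with the longest
    spliced length defines the exon/UTR structure. Genes with no
    transcript features but direct exon children are accepted.
    """
    db = _gff_db(path)
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        transcripts = list(db.children(gene, featuretype=("mRNA", "transcript")))
        if transcripts:
            best, best_len = None, -1
            for tr in transcripts:
                exons = [(f.start, f.end) for f in db.children(tr, featuretype="exon")]
                spliced = sum(e - s + 1 for s, e in exons)
                if spliced > best_len:
                    best, best_len = tr, spliced
            exons = [(f.start, f.end) for f in db.children(best, featuretype="exon")]
            utr5 = [
                (f.start, f.end)
                for f in db.children(best, featuretype="five_prime_UTR")
            ]
            utr3 = [
                (f.start, f.end)
                for f in db.children(best, featuretype="three_prime_UTR")
            ]
        else:
            exons = [(f.start, f.end) for f in db.children(gene, featuretype="exon")]
            utr5 = [
                (f.start, f.end)
                for f in db.children(gene, featuretype="five_prime_UTR")
            ]
            utr3 = [
                (f.start, f.end)
                for f in db.children(gene, featuretype="three_prime_UTR")
            ]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand if gene.strand in ("+", "-") else "+",
                exons=sorted(exons),
                utr5=sorted(utr5),
                utr3=sorted(utr3),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Homolog table


def read_homolog_table(path: str | Path) -> list[HomologGroup]:
    """Read the cross-assembly homologous-TE table (TSV).

    Columns: ``nonredundant_id``, ``assembly``, ``te_id``,
    ``source_assembly``. Each (assembly, te_id) pair may belong to at most
    one nonredundant group.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"nonredundant_id", "assembly", "te_id", "source_assembly"}
    if not required.issubset(df.columns):
        raise AnnotationError(
            f"{path}: homolog table missing columns {sorted(required - set(df.columns))}"
        )
    seen: dict[tuple[str, str], str] = {}
    groups: list[HomologGroup] = []
    for nr_id, sub in df.groupby("nonredundant_id", sort=False):
        members = []
        for _, row in sub.iterrows():
            key = (row["assembly"], row["te_id"])
            if key in seen and seen[key] != nr_id:
                raise AnnotationError(
                    f"{path}: TE {key} claimed by groups {seen[key]} and {nr_id}"
                )
            seen[key] = nr_id
            members.append(key)
        source = sub["source_assembly"].iloc[0]
        groups.append(
            HomologGroup(nonredundant_id=nr_id, members=members, source_assembly=source)
        )
    return groups


def write_homolog_table(groups: Iterable[HomologGroup], path: str | Path) -> None:
    rows = [
        {
            "nonredundant_id": g.nonredundant_id,
            "assembly": asm,
            "te_id": te_id,
            "source_assembly": g.source_assembly,
        }
        for g in groups
        for asm, te_id in g.members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Call matrix


class CallMatrix:
    """TE x sample matrix of presence calls with optional probabilities.

    ``labels`` holds strings from :data:`LABELS`; ``probabilities`` (same
    shape, optional) holds the classifier's probability of presence.
    """

    def __init__(
        self,
        labels: pd.DataFrame,
        probabilities: pd.DataFrame | None = None,
    ) -> None:
        bad = set(np.unique(labels.values.astype(str))) - set(LABELS)
        if bad:
            raise AnnotationError(f"unknown call labels: {sorted(bad)}")
        if probabilities is not None:
            if not labels.index.equals(probabilities.index) or not labels.columns.equals(
                probabilities.columns
            ):
                raise AnnotationError("labels/probabilities axes differ")
        self.labels = labels.astype(str)
        self.probabilities = probabilities

    @property
    def te_ids(self) -> pd.Index:
        return self.labels.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.labels.columns

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CallMatrix):
            return NotImplemented
        if not self.labels.equals(other.labels):
            return False
        if (self.probabilities is None) != (other.probabilities is None):
            return False
        if self.probabilities is not None:
            return self.probabilities.equals(other.probabilities)
        return True

    def ambiguous_fraction(self) -> pd.Series:
        """Per-TE fraction of ambiguous calls among non-missing cells."""
        nonmissing = (self.labels != MISSING).sum(axis=1)
        ambiguous = (self.labels == AMBIGUOUS).sum(axis=1)
        with np.errstate(invalid="ignore"):
            return ambiguous / nonmissing.replace(0, np.nan)

    def check_thresholds(self, absent_max: float = 0.3, present_min: float = 0.7) -> None:
        """Assert stored labels are consistent with stored probabilities."""
        if self.probabilities is None:
            return
        p = self.probabilities.values
        lab = self.labels.values
        has_p = ~np.isnan(p)
        expect = np.where(
            p >= present_min, PRESENT, np.where(p <= absent_max, ABSENT, AMBIGUOUS)
        )
        ok = (~has_p) | (lab == expect) | (lab == MISSING)
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise AnnotationError(
                f"label {lab[i, j]!r} inconsistent with probability {p[i, j]} "
                f"at TE {self.te_ids[i]}, sample {self.sample_ids[j]}"
            )

    # -- serialization: TSV, cells "label" or "label,prob", missing -> "NA"

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("te_id\t" + "\t".join(map(str, self.sample_ids)) + "\n")
            probs = self.probabilities
            for i, te in enumerate(self.te_ids):
                cells = []
                for j in range(len(self.sample_ids)):
                    lab = self.labels.iat[i, j]
                    if lab == MISSING:
                        cells.append("NA")
                        continue
                    if probs is not None and not np.isnan(probs.iat[i, j]):
                        cells.append(f"{lab},{float(probs.iat[i, j])!r}")
                    else:
                        cells.append(lab)
                fh.write(str(te) + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "CallMatrix":
        df = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
        labels = pd.DataFrame(index=df.index, columns=df.columns, dtype=object)
        probs = pd.DataFrame(
            np.nan, index=df.index, columns=df.columns, dtype=float
        )
        any_prob = False
        for i in range(df.shape[0]):
            for j in range(df.shape[1]):
                tok = df.iat[i, j]
                if tok == "NA":
                    labels.iat[i, j] = MISSING
                    continue
                lab, _, p = tok.partition(",")
                if lab not in LABELS:
                    raise AnnotationError(
                        f"{path}: unknown call label token {tok!r} at row "
                        f"{df.index[i]}, column {df.columns[j]}"
                    )
                labels.iat[i, j] = lab
                if p:
                    probs.iat[i, j] = float(p)
                    any_prob = True
        return cls(labels, probs if any_prob else None)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into a 1-based inclusive interval table."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": int, "end": int},
    )
    df["start"] = df["start"] + 1  # 0-based half-open -> 1-based inclusive
    return df


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write a 1-based inclusive interval table as BED (0-based half-open)."""
    out = intervals.copy()
    out["start"] = out["start"] - 1
    cols = ["chrom", "start", "end"] + [
        c for c in out.columns if c not in ("chrom", "start", "end")
    ]
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or adjacent 1-based inclusive intervals per chrom."""
    merged = []
    for chrom, sub in intervals.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append((chrom, cur_s, cur_e))
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])
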
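"""Domain types, table I/O, annotation joining, and branch regrouping.

Genes carry a phylostratum (evolutionary branch of origin, with an assigned
divergence time in Mya), coordinates, sequence lengths, variant-burden
scores, and — for disease genes — the set of organ-phenotype (OP) systems
whose abnormalities their defects produce.

Coordinates are 1-based inclusive (Ensembl convention). All interval tables
consumed together must share one genome assembly; no coordinate lifting is
performed here.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from genestrata.errors import ConfigurationError, TableFormatError, ValidationError

logger = logging.getLogger(__name__)

#: Flags a gene record may carry; filtering drops genes by flag.
KNOWN_FLAGS = {"mitochondrial", "unplaced", "rna_gene", "neoplasm_only", "par"}

#: Reproductive classification labels.
REPRO_CLASSES = ("none", "male", "female", "both")

#: The 22 organ-phenotype (OP) systems, ordered by disease-gene fraction in
#: the reference annotation. OP1 is the nervous system, OP7 the genitourinary
#: (reproductive) system.
DEFAULT_OP_LABELS: tuple[str, ...] = (
    "nervous system",                # OP1
    "head and neck",                 # OP2
    "musculoskeletal system",        # OP3
    "eye",                           # OP4
    "metabolism/homeostasis",        # OP5
    "digestive system",              # OP6
    "genitourinary system",          # OP7
    "integument",                    # OP8
    "cardiovascular system",         # OP9
    "growth",                        # OP10
    "ear",                           # OP11
    "respiratory system",            # OP12
    "limbs",                         # OP13
    "blood and blood-forming tissues",  # OP14
    "immune system",                 # OP15
    "endocrine system",              # OP16
    "connective tissue",             # OP17
    "prenatal development or birth",    # OP18
    "breast",                        # OP19
    "thoracic cavity",               # OP20
    "voice",                         # OP21
    "cellular phenotype",            # OP22
)


@dataclass(frozen=True)
class Phylostratum:
    """A named gene-age branch with an assigned divergence time.

    ``age_mya`` is the node age of the branch on the species tree
    (TimeTree-style), used as the time term in rate and growth analyses.
    """

    id: str
    name: str
    age_mya: float
    merged_into: str | None = None

    def __post_init__(self) -> None:
        if self.age_mya <= 0:
            raise ValidationError(f"stratum {self.id}: age_mya must be positive")


#: Packaged default branch structure (br0 oldest .. br6 youngest) with
#: TimeTree-style node ages in Mya; user-overridable everywhere.
DEFAULT_PHYLOSTRATA: tuple[Phylostratum, ...] = (
    Phylostratum("br0", "Euteleostomi", 435.0),
    Phylostratum("br1", "Tetrapoda", 352.0),
    Phylostratum("br2", "Amniota", 312.0),
    Phylostratum("br3", "Mammalia", 177.0),
    Phylostratum("br4", "Theria", 159.0),
    Phylostratum("br5", "Eutheria", 99.0),
    Phylostratum("br6", "Primate", 74.0),
)

#: Default collapse of the seven branches into four major phylostrata.
MAJOR_STRATA_SCHEME: dict[str, str] = {
    "br0": "Euteleostomi",
    "br1": "Tetrapoda",
    "br2": "Amniota",
    "br3": "Eutheria",
    "br4": "Eutheria",
    "br5": "Eutheria",
    "br6": "Eutheria",
}


class OPCatalog:
    """Ordered catalogue of the 22 organ-phenotype system ids and labels."""

    def __init__(self, labels: Sequence[str] = DEFAULT_OP_LABELS) -> None:
        if len(labels) != 22:
            raise ValidationError(f"expected 22 OP systems, got {len(labels)}")
        self.ids: tuple[str, ...] = tuple(f"OP{i + 1}" for i in range(len(labels)))
        self.labels: dict[str, str] = dict(zip(self.ids, labels))

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, op_id: str) -> bool:
        return op_id in self.labels

    def label(self, op_id: str) -> str:
        return self.labels[op_id]


@dataclass
class GeneRecord:
    """One gene: coordinates, age branch, lengths, burdens, disease annotation.

    Burden fields follow the predictors used in the disease-state regression:
    ``dnv_burden`` (D) is the gene-wise count of predicted-deleterious de novo
    germline variants across trios, ``rare_burden`` (R) the population
    rare-variant burden, ``plof_burden`` the ultrarare predicted
    loss-of-function burden score. ``kaks`` maps a species pair (e.g.
    ``"chimp"``) to the pairwise Ka/Ks ratio.
    """

    gene_id: str
    symbol: str = ""
    chromosome: str = ""
    start: int = 1
    end: int = 1
    protein_length: float | None = None
    gene_length: float | None = None
    branch: str | None = None
    dnv_burden: float | None = None
    rare_burden: float | None = None
    plof_burden: float | None = None
    kaks: dict[str, float] = field(default_factory=dict)
    is_disease: int = 0
    op_set: frozenset[str] = frozenset()
    repro_class: str = "none"
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end ({self.end}) < start ({self.start})"
            )
        if self.repro_class not in REPRO_CLASSES:
            raise ValidationError(
                f"gene {self.gene_id}: bad repro_class {self.repro_class!r}"
            )
        if len(self.op_set) > 22:
            raise ValidationError(f"gene {self.gene_id}: more than 22 OP systems")
        if bool(self.op_set) != bool(self.is_disease):
            raise ValidationError(
                f"gene {self.gene_id}: op_set must be nonempty iff is_disease=1"
            )


@dataclass(frozen=True)
class DiseaseAnnotationRow:
    """One phenotype-to-gene annotation line mapped to an OP system."""

    hpo_id: str
    hpo_name: str
    gene_id: str
    gene_symbol: str
    op_system: str


class Cohort:
    """The joined gene × annotation table every analysis stage consumes."""

    def __init__(
        self,
        genes: Iterable[GeneRecord],
        phylostrata: Sequence[Phylostratum] = DEFAULT_PHYLOSTRATA,
        catalog: OPCatalog | None = None,
    ) -> None:
        self.genes: list[GeneRecord] = list(genes)
        self.phylostrata: list[Phylostratum] = list(phylostrata)
        self.catalog = catalog or OPCatalog()
        ids = [g.gene_id for g in self.genes]
        dupes = [k for k, c in Counter(ids).items() if c > 1]
        if dupes:
            raise ValidationError(f"duplicate gene ids: {dupes[:5]}")
        ages = [s.age_mya for s in self.phylostrata]
        if any(a <= b for a, b in zip(ages, ages[1:])):
            raise ValidationError("phylostrata ages must strictly decrease old -> young")
        known = {s.id for s in self.phylostrata}
        for g in self.genes:
            if g.branch is not None and g.branch not in known:
                raise ValidationError(
                    f"gene {g.gene_id}: unknown branch {g.branch!r}"
                )

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def stratum_ages(self) -> dict[str, float]:
        return {s.id: s.age_mya for s in self.phylostrata}

    def age_of(self, gene: GeneRecord) -> float | None:
        return self.stratum_ages.get(gene.branch) if gene.branch else None

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a DataFrame (one row per gene) for statistics."""
        ages = self.stratum_ages
        rows = []
        for g in self.genes:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "symbol": g.symbol,
                    "chrom": g.chromosome,
                    "start": g.start,
                    "end": g.end,
                    "protein_length": g.protein_length,
                    "gene_length": g.gene_length,
                    "branch": g.branch,
                    "age_mya": ages.get(g.branch) if g.branch else None,
                    "dnv_burden": g.dnv_burden,
                    "rare_burden": g.rare_burden,
                    "plof_burden": g.plof_burden,
                    "kaks_chimp": g.kaks.get("chimp"),
                    "is_disease": g.is_disease,
                    "n_op": len(g.op_set),
                    "op_set": ",".join(sorted(g.op_set, key=_op_sort_key)),
                    "repro_class": g.repro_class,
                    "flags": ",".join(sorted(g.flags)),
                }
            )
        return pd.DataFrame(rows)


def _op_sort_key(op_id: str) -> int:
    return int(op_id[2:]) if op_id.startswith("OP") else 0


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

GENE_TABLE_COLUMNS = (
    "gene_id",
    "symbol",
    "chrom",
    "start",
    "end",
    "protein_length",
    "gene_length",
    "branch",
    "dnv_burden",
    "rare_burden",
    "plof_burden",
    "kaks_chimp",
    "flags",
)

_REQUIRED_GENE_COLUMNS = ("gene_id", "chrom", "start", "end")


def read_gene_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    phylostrata: Sequence[Phylostratum] = DEFAULT_PHYLOSTRATA,
) -> Cohort:
    """Read a tab-separated gene table into a Cohort (without annotations).

    ``dialect`` maps canonical column names to the file's actual header
    names. Optional numeric fields that are empty stay absent (None), never
    zero. Columns named ``kaks_<pair>`` populate the per-pair Ka/Ks map.
    """
    dialect = dict(dialect or {})
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rename = {v: k for k, v in dialect.items()}
    df = df.rename(columns=rename)
    for col in _REQUIRED_GENE_COLUMNS:
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"{path}: duplicate gene_id values {dupes[:5]}")

    kaks_cols = [c for c in df.columns if c.startswith("kaks_")]
    genes = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        kaks = {}
        for c in kaks_cols:
            v = _opt_float(d.get(c))
            if v is not None:
                kaks[c[len("kaks_"):]] = v
        flags = frozenset(f for f in (d.get("flags") or "").split(",") if f)
        op_set = frozenset(s for s in (d.get("op_set") or "").split(",") if s)
        genes.append(
            GeneRecord(
                gene_id=d["gene_id"],
                symbol=d.get("symbol") or "",
                chromosome=d["chrom"],
                start=int(d["start"]),
                end=int(d["end"]),
                protein_length=_opt_float(d.get("protein_length")),
                gene_length=_opt_float(d.get("gene_length")),
                branch=(d.get("branch") or None),
                dnv_burden=_opt_float(d.get("dnv_burden")),
                rare_burden=_opt_float(d.get("rare_burden")),
                plof_burden=_opt_float(d.get("plof_burden")),
                kaks=kaks,
                is_disease=int(d.get("is_disease") or 0),
                op_set=op_set,
                repro_class=d.get("repro_class") or "none",
                flags=flags,
            )
        )
    return Cohort(genes, phylostrata=phylostrata)


def _opt_float(value: str | None) -> float | None:
    if value is None or value == "":
        return None
    return float(value)


def write_gene_table(cohort: Cohort, path: str | Path) -> None:
    """Write a Cohort as a TSV that `read_gene_table` reproduces exactly."""
    rows = []
    for g in cohort.genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "symbol": g.symbol,
                "chrom": g.chromosome,
                "start": g.start,
                "end": g.end,
                "protein_length": _fmt(g.protein_length),
                "gene_length": _fmt(g.gene_length),
                "branch": g.branch or "",
                "dnv_burden": _fmt(g.dnv_burden),
                "rare_burden": _fmt(g.rare_burden),
                "plof_burden": _fmt(g.plof_burden),
                **{f"kaks_{k}": _fmt(v) for k, v in sorted(g.kaks.items())},
                "is_disease": g.is_disease,
                "op_set": ",".join(sorted(g.op_set, key=_op_sort_key)),
                "repro_class": g.repro_class,
                "flags": ",".join(sorted(g.flags)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    return repr(float(value))


def read_strata_table(path: str | Path) -> list[Phylostratum]:
    """Read a branch-age table (TSV: id, name, age_mya), ordered old->young."""
    df = pd.read_csv(path, sep="\t")
    for col in ("id", "name", "age_mya"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    return [
        Phylostratum(str(r.id), str(r.name), float(r.age_mya))
        for r in df.itertuples(index=False)
    ]


def read_op_mapping(path: str | Path) -> dict[str, str]:
    """Read a term -> OP-system mapping table (TSV: hpo_id, op_system)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("hpo_id", "op_system"):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    return dict(zip(df["hpo_id"].astype(str), df["op_system"].astype(str)))


def read_hpo_annotations(
    path: str | Path,
    mapping: Mapping[str, str],
    catalog: OPCatalog | None = None,
) -> list[DiseaseAnnotationRow]:
    """Read a phenotype_to_genes-style TSV and map terms to OP systems.

    Rows whose term has no OP mapping are dropped (count logged); output is
    deduplicated on (gene_id, op_system), keeping the first occurrence.
    """
    if not mapping:
        raise ConfigurationError("empty term -> OP mapping")
    catalog = catalog or OPCatalog()
    try:
        df = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, comment="#"
        )
    except OSError as exc:
        raise OSError(f"cannot read annotation file {path}: {exc}") from exc
    if df.shape[1] < 4:
        raise TableFormatError(
            f"{path}: expected >= 4 columns (hpo_id, hpo_name, gene_id, gene_symbol)"
        )
    cols = list(df.columns[:4])
    out: list[DiseaseAnnotationRow] = []
    seen: set[tuple[str, str]] = set()
    dropped = 0
    for row in df.itertuples(index=False):
        hpo_id, hpo_name, gene_id, gene_symbol = (getattr(row, c) for c in cols)
        op = mapping.get(hpo_id)
        if op is None:
            dropped += 1
            continue
        if op not in catalog:
            raise ValidationError(f"{path}: mapped OP {op!r} not in catalogue")
        key = (gene_id, op)
        if key in seen:
            continue
        seen.add(key)
        out.append(DiseaseAnnotationRow(hpo_id, hpo_name, gene_id, gene_symbol, op))
    if dropped:
        logger.info("read_hpo_annotations: dropped %d unmapped rows", dropped)
    return out


def attach_annotations(
    cohort: Cohort, annotations: Iterable[DiseaseAnnotationRow]
) -> Cohort:
    """Set is_disease/op_set on cohort genes from annotation rows."""
    by_gene: dict[str, set[str]] = {}
    for row in annotations:
        by_gene.setdefault(row.gene_id, set()).add(row.op_system)
    genes = []
    for g in cohort.genes:
        ops = frozenset(by_gene.get(g.gene_id, ()))
        genes.append(
            dataclasses.replace(g, op_set=ops, is_disease=int(bool(ops)))
        )
    return Cohort(genes, cohort.phylostrata, cohort.catalog)


# ---------------------------------------------------------------------------
# Filtering, reproductive classification, branch regrouping
# ---------------------------------------------------------------------------


def apply_exclusion_filters(cohort: Cohort, drop_flags: set[str]) -> Cohort:
    """Remove genes carrying any flag in drop_flags; removals logged per flag.

    The standard cleaning step drops mitochondrial genes, unplaced genes,
    RNA genes and neoplasm-only genes before age-stratified analyses.
    """
    counts = {f: 0 for f in drop_flags}
    kept = []
    for g in cohort.genes:
        hit = g.flags & drop_flags
        if hit:
            for f in hit:
                counts[f] += 1
        else:
            kept.append(g)
    for f, c in sorted(counts.items()):
        if c:
            logger.info("apply_exclusion_filters: dropped %d genes for flag %s", c, f)
    out = Cohort(kept, cohort.phylostrata, cohort.catalog)
    out.removal_counts = counts  # type: ignore[attr-defined]
    return out


_FEMALE_RE = re.compile(r"female", re.IGNORECASE)
# "male" only when not the tail of "female" (word-boundary-aware guard)
_MALE_RE = re.compile(r"(?<![fF][eE])male", re.IGNORECASE)


def classify_reproductive(
    annotations: Iterable[DiseaseAnnotationRow],
    keywords: Sequence[str] = ("reproduct", "male", "female"),
    exclusions: Sequence[str] = ("neoplasm",),
    male_in_female_guard: bool = True,
) -> dict[str, str]:
    """Classify genes as male/female/both reproductive from term names.

    Case-insensitive substring matching on the phenotype term name:
    ``female`` assigns female; ``male`` assigns male only when the match is
    not the tail of "female" (the guard is configurable because a plain grep
    would also hit the substring); ``reproduct`` alone assigns both. A gene
    matched in both sexes is classified ``both``. Rows whose name contains an
    exclusion term (default "neoplasm") are removed before matching.
    """
    kw = {k.lower() for k in keywords}
    male_re = _MALE_RE if male_in_female_guard else re.compile(r"male", re.IGNORECASE)
    hits: dict[str, set[str]] = {}
    for row in annotations:
        name = row.hpo_name.lower()
        if any(x.lower() in name for x in exclusions):
            continue
        flags = hits.setdefault(row.gene_id, set())
        if "female" in kw and _FEMALE_RE.search(name):
            flags.add("female")
        if "male" in kw and male_re.search(name):
            flags.add("male")
        if "reproduct" in kw and "reproduct" in name:
            flags.add("reproduct")
    out: dict[str, str] = {}
    for gene_id, flags in hits.items():
        if "male" in flags and "female" in flags:
            out[gene_id] = "both"
        elif "male" in flags:
            out[gene_id] = "male"
        elif "female" in flags:
            out[gene_id] = "female"
        elif "reproduct" in flags:
            out[gene_id] = "both"
    return {g: c for g, c in out.items()}


def apply_repro_classes(cohort: Cohort, classes: Mapping[str, str]) -> Cohort:
    """Return a cohort with repro_class set from a gene_id -> class map."""
    genes = [
        dataclasses.replace(g, repro_class=classes.get(g.gene_id, "none"))
        for g in cohort.genes
    ]
    return Cohort(genes, cohort.phylostrata, cohort.catalog)


def regroup_branches(cohort: Cohort, min_genes: int = 100) -> Cohort:
    """Merge sparsely populated branches into their adjacent older branch.

    Iterating youngest-first, any stratum with fewer than ``min_genes``
    genes is merged into the adjacent older stratum (which keeps its own id
    and age), until every remaining stratum holds at least ``min_genes``
    genes or a single stratum remains. Idempotent.
    """
    if not cohort.genes:
        raise ValidationError("cannot regroup an empty cohort")
    strata = list(cohort.phylostrata)
    assign = {s.id: s.id for s in strata}  # original id -> current id
    counts = Counter(assign[g.branch] for g in cohort.genes if g.branch)

    def current_order() -> list[str]:
        seen = []
        for s in strata:
            cur = assign[s.id]
            if cur not in seen:
                seen.append(cur)
        return seen

    while True:
        order = current_order()
        if len(order) <= 1:
            break
        merged = False
        for sid in reversed(order):  # youngest first
            idx = order.index(sid)
            if counts.get(sid, 0) < min_genes and idx > 0:
                target = order[idx - 1]
                for orig, cur in assign.items():
                    if cur == sid:
                        assign[orig] = target
                counts[target] = counts.get(target, 0) + counts.pop(sid, 0)
                merged = True
                break
        if not merged:
            break

    order = current_order()
    by_id = {s.id: s for s in strata}
    new_strata = [
        dataclasses.replace(
            by_id[sid],
            merged_into=None,
        )
        for sid in order
    ]
    genes = [
        dataclasses.replace(g, branch=assign[g.branch]) if g.branch else g
        for g in cohort.genes
    ]
    return Cohort(genes, new_strata, cohort.catalog)


def collapse_to_major_strata(
    cohort: Cohort, scheme: Mapping[str, str] | None = None
) -> Cohort:
    """Relabel branches into major phylostrata (default: the four-group scheme
    Euteleostomi / Tetrapoda / Amniota / Eutheria). Conserves gene counts.
    """
    scheme = dict(scheme or MAJOR_STRATA_SCHEME)
    missing = [s.id for s in cohort.phylostrata if s.id not in scheme]
    if missing:
        raise ConfigurationError(f"collapse scheme omits branches: {missing}")
    # group age = oldest member branch's age; order groups old -> young
    group_age: dict[str, float] = {}
    order: list[str] = []
    for s in cohort.phylostrata:
        grp = scheme[s.id]
        if grp not in group_age:
            group_age[grp] = s.age_mya
            order.append(grp)
    new_strata = [Phylostratum(grp, grp, group_age[grp]) for grp in order]
    genes = [
        dataclasses.replace(g, branch=scheme[g.branch]) if g.branch else g
        for g in cohort.genes
    ]
    return Cohort(genes, new_strata, cohort.catalog)


def write_manifest(
    path: str | Path,
    inputs: Mapping[str, str],
    parameters: Mapping[str, object],
    seed: int | None,
) -> None:
    """Write a JSON run manifest (inputs, parameters, seed, versions)."""
    import numpy
    import scipy

    manifest = {
        "inputs": dict(inputs),
        "parameters": {k: _jsonable(v) for k, v in parameters.items()},
        "seed": seed,
        "versions": {
            "genestrata": _pkg_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _jsonable(value):
    if isinstance(value, (str, int, float, bool)) or value is None:
        return value
    if isinstance(value, Mapping):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in value]
    return str(value)


def _pkg_version() -> str:
    from genestrata import __version__

    return __version__
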
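"""Input descriptions: the minimal descriptions table (MDT), per-file configs
and the controlled tissue/system vocabulary.

The MDT is a TSV with one row per input data file carrying biological
(biosample term/type, life stage, assay), source (project, DOI) and file
(data path, config path) information.  A file config is a flat ``key = value``
text file that maps input columns (by 1-based position or header name) onto
the standard output fields of one datatype and records the input dialect
(delimiter, header presence, coordinate base, chromosome naming style).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

DATATYPES = ("intervals", "qtl", "interactions")

#: Accepted genome-build spellings, normalized to the canonical label.
GENOME_BUILDS = {
    "grch37": "GRCh37/hg19",
    "hg19": "GRCh37/hg19",
    "grch37/hg19": "GRCh37/hg19",
    "grch38": "GRCh38/hg38",
    "hg38": "GRCh38/hg38",
    "grch38/hg38": "GRCh38/hg38",
}

MDT_REQUIRED_COLUMNS = (
    "track_id",
    "datatype",
    "biosample_term",
    "assay_type",
    "genome_build",
    "data_source",
    "file_path",
    "config_path",
)

#: Optional MDT columns recognized as first-class descriptor fields; anything
#: else lands in ``TrackDescriptor.extra`` in column order.
MDT_OPTIONAL_COLUMNS = ("biosample_type", "life_stage", "doi")

#: Input fields a config may map, per datatype.  ``pos`` is a single-position
#: alternative to start/end (QTLs typically report one coordinate).
MAPPABLE_FIELDS = {
    "intervals": ("chrom", "start", "end", "name", "score", "strand"),
    "qtl": (
        "chrom", "pos", "start", "end", "variant_id", "ref", "alt",
        "beta", "se", "pvalue", "fdr", "alt_allele_freq", "target_id", "tissue",
    ),
    "interactions": (
        "chrom1", "start1", "end1", "chrom2", "start2", "end2",
        "score", "value", "pvalue", "experiment", "color", "strand1", "strand2",
    ),
}

REQUIRED_FIELDS = {
    "intervals": ("chrom", "start", "end"),
    # ``pos`` or (start, end) — checked specially in validate_required().
    "qtl": ("chrom", "variant_id", "ref", "alt", "beta", "pvalue", "target_id"),
    "interactions": ("chrom1", "start1", "end1", "chrom2", "start2", "end2"),
}


@dataclass
class TrackDescriptor:
    """One MDT row: everything needed to harmonize one input file."""

    track_id: str
    datatype: str
    biosample_term: str
    assay_type: str
    genome_build: str
    data_source: str
    file_path: Path
    config_path: Path
    biosample_type: str = ""
    life_stage: str = ""
    doi: str = ""
    extra: dict = field(default_factory=dict)


@dataclass
class FileConfig:
    """Input-to-output column mapping plus dialect attributes.

    ``column_map`` keys are standard field names; values are the input column
    as given in the config — an ``int`` (1-based position) or a ``str``
    (header name, resolved against the header at read time).
    """

    column_map: dict
    delimiter: str = "\t"
    has_header: bool = True
    coordinate_base: int = 1
    chrom_style: str = "auto"
    passthrough_columns: list = field(default_factory=list)


@dataclass(frozen=True)
class CategoryAssignment:
    tissue_category: str
    system_category: str


def _check_build(value: str) -> str:
    try:
        return GENOME_BUILDS[value.strip().lower()]
    except KeyError:
        raise ValidationError(
            f"unsupported genome_build {value!r}; supported: GRCh37/hg19, GRCh38/hg38"
        ) from None


def parse_mdt(path) -> list[TrackDescriptor]:
    """Parse a minimal descriptions table into one descriptor per data row.

    Every problem found is collected and reported together (missing columns,
    bad datatypes/builds, unreadable file or config paths for *all* offending
    rows), so one validation pass surfaces the whole batch's issues.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MDT_REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(
            f"MDT {path} is missing required column(s): {', '.join(missing)}"
        )
    if table.empty:
        logger.warning("MDT %s contains a header but no data rows", path)
        return []

    known = set(MDT_REQUIRED_COLUMNS) | set(MDT_OPTIONAL_COLUMNS)
    extra_cols = [c for c in table.columns if c not in known]
    descriptors, problems = [], []
    for idx, row in table.iterrows():
        rowno = idx + 2  # 1-based, counting the header line
        datatype = row["datatype"].strip().lower()
        if datatype not in DATATYPES:
            problems.append(
                f"row {rowno}: unknown datatype {row['datatype']!r} "
                f"(expected one of {', '.join(DATATYPES)})"
            )
            continue
        try:
            build = _check_build(row["genome_build"])
        except ValidationError as exc:
            problems.append(f"row {rowno}: {exc}")
            continue
        file_path = (path.parent / row["file_path"]).resolve()
        config_path = (path.parent / row["config_path"]).resolve()
        for label, p in (("file_path", file_path), ("config_path", config_path)):
            if not p.is_file():
                problems.append(f"row {rowno}: {label} {p} is not a readable file")
        descriptors.append(
            TrackDescriptor(
                track_id=row["track_id"],
                datatype=datatype,
                biosample_term=row["biosample_term"],
                assay_type=row["assay_type"],
                genome_build=build,
                data_source=row["data_source"],
                file_path=file_path,
                config_path=config_path,
                biosample_type=row.get("biosample_type", ""),
                life_stage=row.get("life_stage", ""),
                doi=row.get("doi", ""),
                extra={c: row[c] for c in extra_cols},
            )
        )
    if problems:
        raise ValidationError("MDT validation failed:\n  " + "\n  ".join(problems))
    return descriptors


def write_mdt(descriptors: list[TrackDescriptor], path) -> None:
    """Serialize descriptors back to MDT TSV (inverse of :func:`parse_mdt`)."""
    path = Path(path)
    extra_cols: list[str] = []
    for d in descriptors:
        for c in d.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    columns = list(MDT_REQUIRED_COLUMNS) + list(MDT_OPTIONAL_COLUMNS) + extra_cols
    rows = []
    for d in descriptors:
        row = {
            "track_id": d.track_id,
            "datatype": d.datatype,
            "biosample_term": d.biosample_term,
            "assay_type": d.assay_type,
            "genome_build": d.genome_build,
            "data_source": d.data_source,
            "file_path": str(d.file_path),
            "config_path": str(d.config_path),
            "biosample_type": d.biosample_type,
            "life_stage": d.life_stage,
            "doi": d.doi,
        }
        row.update({c: d.extra.get(c, "") for c in extra_cols})
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


_DELIM_NAMES = {"tab": "\t", "\\t": "\t", "comma": ",", "space": " ",
                "semicolon": ";", "pipe": "|"}
_BOOL = {"true": True, "yes": True, "1": True, "false": False, "no": False, "0": False}


def parse_file_config(path, datatype: str) -> FileConfig:
    """Parse a flat key-value file config.

    Grammar (one statement per line; ``#`` starts a comment)::

        delimiter = tab            # tab|comma|space|semicolon|pipe or a literal
        has_header = true
        coordinate_base = 1        # 0 or 1
        chrom_style = auto         # auto|bare|chr_prefixed
        passthrough = colA, colB   # input columns preserved after standard fields
        2 -> chrom                 # input column (1-based position or name)
        pos_name -> pos            #   mapped to a standard field

    Defaults: tab-delimited, header present, 1-based coordinates, auto
    chromosome style, no passthrough.
    """
    if datatype not in DATATYPES:
        raise ValidationError(f"unknown datatype {datatype!r}")
    valid = MAPPABLE_FIELDS[datatype]
    column_map: dict = {}
    opts = {"delimiter": "\t", "has_header": True, "coordinate_base": 1,
            "chrom_style": "auto"}
    passthrough: list = []
    path = Path(path)
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        where = f"{path}:{lineno}"
        if "->" in line:
            src, _, dst = line.partition("->")
            src, dst = src.strip(), dst.strip()
            if dst not in valid:
                raise ValidationError(
                    f"{where}: {dst!r} is not a standard {datatype} field; "
                    f"valid fields: {', '.join(valid)}"
                )
            if dst in column_map:
                raise ValidationError(
                    f"{where}: output field {dst!r} mapped more than once"
                )
            col = int(src) if src.isdigit() else src
            if col in column_map.values():
                raise ValidationError(
                    f"{where}: input column {src!r} mapped to two output fields"
                )
            column_map[dst] = col
        elif "=" in line:
            key, _, value = line.partition("=")
            key, value = key.strip().lower(), value.strip()
            if key == "delimiter":
                opts["delimiter"] = _DELIM_NAMES.get(value.lower(), value)
                if len(opts["delimiter"]) != 1:
                    raise ValidationError(f"{where}: delimiter must be one character")
            elif key == "has_header":
                try:
                    opts["has_header"] = _BOOL[value.lower()]
                except KeyError:
                    raise ValidationError(f"{where}: has_header must be true/false") from None
            elif key == "coordinate_base":
                if value not in ("0", "1"):
                    raise ValidationError(f"{where}: coordinate_base must be 0 or 1")
                opts["coordinate_base"] = int(value)
            elif key == "chrom_style":
                if value not in ("auto", "bare", "chr_prefixed"):
                    raise ValidationError(
                        f"{where}: chrom_style must be auto, bare or chr_prefixed"
                    )
                opts["chrom_style"] = value
            elif key == "passthrough":
                for item in value.split(","):
                    item = item.strip()
                    if item:
                        passthrough.append(int(item) if item.isdigit() else item)
            else:
                raise ValidationError(f"{where}: unknown config key {key!r}")
        else:
            raise ValidationError(f"{where}: cannot parse line {raw!r}")

    cfg = FileConfig(column_map=column_map, passthrough_columns=passthrough, **opts)
    validate_required(cfg, datatype, str(path))
    return cfg


def validate_required(cfg: FileConfig, datatype: str, where: str = "config") -> None:
    """Check that every standard field the datatype requires is mapped."""
    missing = [f for f in REQUIRED_FIELDS[datatype] if f not in cfg.column_map]
    if datatype == "qtl":
        if "pos" not in cfg.column_map and not (
            "start" in cfg.column_map and "end" in cfg.column_map
        ):
            missing.append("pos (or start+end)")
    if missing:
        raise ValidationError(
            f"{where}: missing required {datatype} field mapping(s): "
            + ", ".join(missing)
        )


def load_vocabulary(path=None) -> dict:
    """Load the term -> (tissue_category, system_category) vocabulary.

    Bundled vocabulary is used when ``path`` is None. Lookup is
    case-insensitive; the table is keyed on the lower-cased term.
    """
    if path is None:
        source = resources.files("fgharmonize.data").joinpath("vocabulary.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    vocab = {}
    for i, line in enumerate(text.splitlines()):
        if not line.strip() or (i == 0 and line.startswith("term")):
            continue
        term, tissue, system = line.rstrip("\n").split("\t")
        vocab[term.strip().lower()] = CategoryAssignment(tissue, system)
    return vocab


def resolve_categories(biosample_term: str, vocabulary: dict) -> CategoryAssignment:
    """Map a free-text biosample term to standardized tissue/system categories.

    Total on any string input: unmatched terms degrade to
    ``("uncategorized", "uncategorized")`` with a warning, never an error,
    so one unrecognized label cannot block a batch run.
    """
    hit = vocabulary.get(str(biosample_term).strip().lower())
    if hit is None:
        logger.warning(
            "biosample term %r not in vocabulary; categories set to 'uncategorized'",
            biosample_term,
        )
        return CategoryAssignment("uncategorized", "uncategorized")
    return hit
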
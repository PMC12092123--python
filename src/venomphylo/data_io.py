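"""Input/output layer: calibrated trees, validated CSV tables, YAML configs.

Trees are time-calibrated (branch lengths in millions of years, Myr) and
wrapped in :class:`CalibratedPhylogeny`, which caches node depths, tip
lookup tables and clade leaf sets so downstream divergence-time queries are
cheap.  Tabular inputs are plain UTF-8 CSV with a "." decimal separator;
each registered schema maps rows onto the typed records used by the rest of
the pipeline and reports errors with row/column provenance.

Species labels are matched case-insensitively after trimming, with spaces
and underscores interchangeable (newick files conventionally use
underscores where tables use spaces).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import dendropy
import yaml

from .errors import (
    DuplicateLabelError,
    NewickParseError,
    NotUltrametricError,
    SchemaError,
    TaxonLookupError,
    TreeValidationError,
)

INJECTION_ROUTES = ("IP", "IV", "SC", "thorax_cephalothorax", "abdomen")
EXTRACTION_METHODS = (
    "electrical_stimulation",
    "direct_stimulation",
    "gland_extraction",
    "unknown",
)

_LOGGER_NAME = "venomphylo"


def get_logger(name: str = _LOGGER_NAME) -> logging.Logger:
    """Return the package logger (plain-text structured lines on stderr)."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


def normalize_label(label: str) -> str:
    """Canonical matching form of a taxon label.

    Trimmed, lower-cased, spaces folded to underscores.
    """
    return label.strip().lower().replace(" ", "_")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


class CalibratedPhylogeny:
    """Rooted tree with branch lengths in millions of years (Myr).

    The wrapper owns lookups by normalized label (tips and labelled internal
    clades), per-node depths from the root, and per-node leaf sets.  All
    divergence-time operations require the tree to be ultrametric (checked
    on demand via :meth:`require_ultrametric`).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._index()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path) -> "CalibratedPhylogeny":
        """Parse newick text or a path to a newick file."""
        text = None
        if isinstance(source, Path):
            text = source.read_text()
        elif isinstance(source, str):
            if "(" in source or ";" in source:
                text = source
            else:
                text = Path(source).read_text()
        _check_newick_syntax(text)
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            msg = str(exc)
            marker = "Duplicate taxon labels: "
            if marker in msg:
                dups = msg.split(marker, 1)[1].strip().rstrip(".")
                raise DuplicateLabelError(
                    [normalize_label(d) for d in dups.split(", ")]
                ) from exc
            raise NewickParseError(f"newick parse failed: {exc}") from exc
        return cls(tree)

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeValidationError("tree has an unlabelled tip")
            labels.append(leaf.taxon.label)
        seen, dups = set(), set()
        for lab in (normalize_label(x) for x in labels):
            if lab in seen:
                dups.add(lab)
            seen.add(lab)
        if dups:
            raise DuplicateLabelError(sorted(dups))
        for edge in self._tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length {edge.length}"
                )

    def _index(self) -> None:
        self._depth = {}
        root = self._tree.seed_node
        self._depth[root] = root.edge.length or 0.0
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            self._depth[node] = self._depth[node.parent_node] + (
                node.edge.length or 0.0
            )
        self._leafset = {}
        self._tips = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                lab = normalize_label(node.taxon.label)
                self._tips[lab] = node
                self._leafset[node] = frozenset([lab])
            else:
                self._leafset[node] = frozenset().union(
                    *(self._leafset[c] for c in node.child_nodes())
                )
        self._clades = {}
        for node in self._tree.preorder_internal_node_iter():
            if node.label:
                self._clades[normalize_label(node.label)] = node

    # -- basic accessors ----------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length (Myr)."""
        return max(self._depth[t] for t in self._tips.values())

    def node_depth(self, node) -> float:
        return self._depth[node]

    # -- invariants ---------------------------------------------------------

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = [self._depth[t] for t in self._tips.values()]
        span = max(depths) - min(depths)
        return span <= rel_tol * max(max(depths), 1e-300)

    def require_ultrametric(self, rel_tol: float = 1e-6) -> None:
        if not self.is_ultrametric(rel_tol):
            raise NotUltrametricError(
                "operation requires an ultrametric tree; root-to-tip depths "
                "are unequal beyond tolerance"
            )

    # -- lookups ------------------------------------------------------------

    def resolve(self, name: str):
        """Resolve a taxon name to a tip node or a labelled internal clade."""
        key = normalize_label(name)
        if key in self._tips:
            return self._tips[key]
        if key in self._clades:
            return self._clades[key]
        raise TaxonLookupError(name)

    def leafset(self, node) -> frozenset:
        return self._leafset[node]

    def mrca_depth(self, node_a, node_b) -> float:
        """Depth from the root of the MRCA of two (tip or clade) nodes."""
        if node_a is node_b:
            return self._depth[node_a]
        target = self._leafset[node_a] | self._leafset[node_b]
        node = node_a
        while not target <= self._leafset[node]:
            node = node.parent_node
        return self._depth[node]

    def is_nested(self, node_a, node_b) -> bool:
        """True when one node's leaf set contains the other's."""
        a, b = self._leafset[node_a], self._leafset[node_b]
        return a <= b or b <= a

    # -- output -------------------------------------------------------------

    def to_newick(self) -> str:
        """Serialize with shortest round-tripping decimal branch lengths."""

        def emit(node) -> str:
            if node.is_leaf():
                core = node.taxon.label.replace(" ", "_")
            else:
                inner = ",".join(emit(c) for c in node.child_nodes())
                core = f"({inner})" + (
                    node.label.replace(" ", "_") if node.label else ""
                )
            if node.edge.length is not None and node.parent_node is not None:
                core += f":{node.edge.length!r}"
            return core

        return emit(self._tree.seed_node) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def _check_newick_syntax(text: str) -> None:
    """Cheap structural scan so parse errors can name a character offset."""
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError("unbalanced ')'", offset=i)
        elif ch == ";":
            if depth != 0:
                raise NewickParseError(
                    "';' before parentheses balanced", offset=i
                )
    if depth != 0:
        raise NewickParseError("unbalanced '('", offset=len(text) - 1)
    if ";" not in text:
        raise NewickParseError("missing terminating ';'",
                               offset=len(text) - 1)


def read_newick(source: str | Path) -> CalibratedPhylogeny:
    """Read a calibrated tree from newick text or a file path."""
    return CalibratedPhylogeny.from_newick(source)


def write_newick(tree: CalibratedPhylogeny, path: str | Path) -> None:
    tree.write_newick(path)


# ---------------------------------------------------------------------------
# Typed records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssayRecord:
    """One median-lethal-dose measurement.

    LD50 is milligrams of lyophilized venom per kilogram of test subject;
    lower values mean more potent venom.
    """

    species: str
    model_organism: str
    ld50_mg_per_kg: float
    route: str
    lyophilized: bool = True
    row: int | None = None

    def __post_init__(self):
        if not self.ld50_mg_per_kg > 0:
            raise SchemaError(
                f"LD50 must be > 0, got {self.ld50_mg_per_kg}",
                row=self.row, column="ld50_mg_per_kg",
            )
        if self.route not in INJECTION_ROUTES:
            raise SchemaError(
                f"route {self.route!r} not one of {INJECTION_ROUTES}",
                row=self.row, column="route",
            )


@dataclass(frozen=True)
class SpeciesTraits:
    """Per-species morphology and behaviour used by the models."""

    species: str
    body_length_mm: float | None = None
    body_mass_g: float | None = None
    silk_use: bool = False
    venom_yield_mg: float | None = None
    extraction_method: str = "unknown"
    vertebrate_in_diet: bool | None = None
    row: int | None = None

    def __post_init__(self):
        for name in ("body_length_mm", "body_mass_g", "venom_yield_mg"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise SchemaError(f"{name} must be > 0, got {v}",
                                  row=self.row, column=name)
        if self.extraction_method not in EXTRACTION_METHODS:
            raise SchemaError(
                f"extraction_method {self.extraction_method!r} not one of "
                f"{EXTRACTION_METHODS}",
                row=self.row, column="extraction_method",
            )

    def mass_for_model(self, exponent: float = 2.6,
                       coefficient: float = 1.0) -> float:
        """Body mass (g), falling back to the length power law."""
        if self.body_mass_g is not None:
            return self.body_mass_g
        if self.body_length_mm is not None:
            from .allometry import length_to_mass
            return length_to_mass(self.body_length_mm, exponent, coefficient)
        raise SchemaError(
            f"species {self.species!r} has neither mass nor length",
            row=self.row, column="body_mass_g",
        )


@dataclass(frozen=True)
class DietReportRow:
    """One raw diet-report line: qualitative label and/or proportion."""

    species: str
    prey_taxon: str
    rank: str = "class"
    qual_label: str | None = None
    quant_proportion: float | None = None
    row: int | None = None

    def __post_init__(self):
        if self.qual_label is None and self.quant_proportion is None:
            raise SchemaError(
                "diet report row needs a qualitative label or a proportion",
                row=self.row, column="qual_label",
            )
        if self.quant_proportion is not None and not (
            0 <= self.quant_proportion <= 1
        ):
            raise SchemaError(
                f"proportion must be in [0, 1], got {self.quant_proportion}",
                row=self.row, column="quant_proportion",
            )


# ---------------------------------------------------------------------------
# Tabular schemas
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


def _parse_bool(text: str, row: int, column: str) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise SchemaError(f"cannot parse boolean from {text!r}",
                      row=row, column=column)


def _parse_float(text: str, row: int, column: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise SchemaError(f"cannot parse number from {text!r}",
                          row=row, column=column) from None


def _opt(text: str):
    t = text.strip()
    return None if t in ("", "NA", "na", "None") else t


def _make_assay(fields: dict[str, str], row: int) -> AssayRecord:
    return AssayRecord(
        species=fields["species"].strip(),
        model_organism=fields["model_organism"].strip(),
        ld50_mg_per_kg=_parse_float(fields["ld50_mg_per_kg"], row,
                                    "ld50_mg_per_kg"),
        route=fields["route"].strip(),
        lyophilized=_parse_bool(fields.get("lyophilized", "true"), row,
                                "lyophilized"),
        row=row,
    )


def _make_traits(fields: dict[str, str], row: int) -> SpeciesTraits:
    def optf(col):
        raw = _opt(fields.get(col, ""))
        return None if raw is None else _parse_float(raw, row, col)

    vert = _opt(fields.get("vertebrate_in_diet", ""))
    method = _opt(fields.get("extraction_method", "")) or "unknown"
    return SpeciesTraits(
        species=fields["species"].strip(),
        body_length_mm=optf("body_length_mm"),
        body_mass_g=optf("body_mass_g"),
        silk_use=_parse_bool(fields["silk_use"], row, "silk_use"),
        venom_yield_mg=optf("venom_yield_mg"),
        extraction_method=method,
        vertebrate_in_diet=(
            None if vert is None else _parse_bool(vert, row,
                                                  "vertebrate_in_diet")
        ),
        row=row,
    )


def _make_diet_report(fields: dict[str, str], row: int) -> DietReportRow:
    quant = _opt(fields.get("quant_proportion", ""))
    return DietReportRow(
        species=fields["species"].strip(),
        prey_taxon=fields["prey_taxon"].strip(),
        rank=_opt(fields.get("rank", "")) or "class",
        qual_label=_opt(fields.get("qual_label", "")),
        quant_proportion=(
            None if quant is None
            else _parse_float(quant, row, "quant_proportion")
        ),
        row=row,
    )


def _make_class_map_entry(fields: dict[str, str], row: int):
    taxon = fields["prey_taxon"].strip()
    cls = fields["class"].strip()
    if not taxon or not cls:
        raise SchemaError("empty prey_taxon or class", row=row,
                          column="prey_taxon" if not taxon else "class")
    return (taxon, cls)


SCHEMAS = {
    "assays": (("species", "model_organism", "ld50_mg_per_kg", "route"),
               _make_assay),
    "traits": (("species", "silk_use"), _make_traits),
    "diet_reports": (("species", "prey_taxon"), _make_diet_report),
    "taxon_class_map": (("prey_taxon", "class"), _make_class_map_entry),
}


def read_table(path: str | Path, schema_name: str):
    """Read and validate a CSV against a registered schema.

    Returns a list of typed records (``assays`` -> :class:`AssayRecord`,
    ``traits`` -> :class:`SpeciesTraits`, ``diet_reports`` ->
    :class:`DietReportRow`) or, for ``taxon_class_map``, a dict
    ``prey_taxon -> class``.  Row numbers (1-based, header excluded) ride
    along on every record and every :class:`SchemaError`.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(
            f"unknown schema {schema_name!r}; "
            f"registered: {sorted(SCHEMAS)}"
        )
    required, factory = SCHEMAS[schema_name]
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise SchemaError(f"missing required column {col!r}",
                                  column=col)
        records = []
        for i, line in enumerate(reader, start=1):
            records.append(factory(line, i))
    if schema_name == "taxon_class_map":
        return dict(records)
    return records


# ---------------------------------------------------------------------------
# Model-run configuration (YAML)
# ---------------------------------------------------------------------------


def load_yaml_config(path: str | Path) -> dict:
    """Load a YAML config file into a plain dict (safe loader)."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("YAML config must be a mapping at top level")
    return cfg
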
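"""Reading, writing and slicing annotated circular mitochondrial genomes.

Coordinates are 1-based inclusive throughout, matching the convention of
published mitogenome feature tables. A feature with end < start is legal
only on a circular molecule and denotes an origin-spanning interval.
"""

from __future__ import annotations

import csv
import importlib.resources
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO

from .genetics import reverse_complement

PCG_NAMES = frozenset(
    {
        "atp6",
        "atp8",
        "cob",
        "cox1",
        "cox2",
        "cox3",
        "nad1",
        "nad2",
        "nad3",
        "nad4",
        "nad4l",
        "nad5",
        "nad6",
    }
)

CATEGORIES = ("PCG", "tRNA", "rRNA", "control_region", "origin_light")

_VALID_STOPS = {"TAA", "TAG", "AGA", "AGG", "T", "TA"}


class GenomeValidationError(ValueError):
    pass


def _load_name_map() -> dict[str, str]:
    text = (
        importlib.resources.files("mitochar.data")
        .joinpath("gene_names.tsv")
        .read_text()
    )
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    return {r["alias"].upper(): r["canonical"] for r in rows}


def normalize_gene_name(raw: str) -> str | None:
    """Map an annotation label to the package lexicon; None if unknown."""
    name_map = _load_name_map()
    key = raw.strip().upper()
    if key in name_map:
        return name_map[key]
    low = raw.strip()
    lowl = low.lower()
    if lowl in PCG_NAMES or lowl in {"rrns", "rrnl", "cr", "ol"}:
        return {"rrns": "rrnS", "rrnl": "rrnL", "cr": "CR", "ol": "OL"}.get(lowl, lowl)
    if lowl.startswith("trn") and len(low) in (4, 5):
        return "trn" + low[3:]
    return None


def categorize(name: str) -> str | None:
    if name in PCG_NAMES:
        return "PCG"
    if name.startswith("trn"):
        return "tRNA"
    if name in ("rrnS", "rrnL"):
        return "rRNA"
    if name == "CR":
        return "control_region"
    if name == "OL":
        return "origin_light"
    return None


@dataclass
class GeneFeature:
    """One annotated gene interval on the circular molecule.

    strand is "H" (heavy, '+') or "L" (light, '-'); L-strand features are
    encoded on the complement, so their sense sequence is the reverse
    complement of the genome slice.
    """

    name: str
    category: str
    start: int
    end: int
    strand: str
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise GenomeValidationError(f"unknown category {self.category!r}")
        if self.strand not in ("H", "L"):
            raise GenomeValidationError(f"strand must be H or L, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise GenomeValidationError(f"{self.name}: coordinates must be >= 1")
        if (self.anticodon is not None) != (self.category == "tRNA"):
            raise GenomeValidationError(
                f"{self.name}: anticodon present iff category is tRNA"
            )
        if self.category != "PCG" and (self.start_codon or self.stop_codon):
            raise GenomeValidationError(
                f"{self.name}: start/stop codons only allowed on PCGs"
            )
        if self.stop_codon is not None and self.stop_codon not in _VALID_STOPS:
            raise GenomeValidationError(
                f"{self.name}: invalid stop codon {self.stop_codon!r}"
            )


@dataclass
class MitoGenome:
    """A circular mitogenome: optional sequence plus ordered features."""

    id: str
    species: str = ""
    sequence: str | None = None
    length: int | None = None
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        if self.sequence is not None:
            bad = set(self.sequence) - set("ACGTN")
            if bad:
                raise GenomeValidationError(
                    f"ambiguity codes other than N not supported: {sorted(bad)}"
                )
            if self.length is None:
                self.length = len(self.sequence)
            elif self.length != len(self.sequence):
                raise GenomeValidationError(
                    f"declared length {self.length} != sequence length "
                    f"{len(self.sequence)}"
                )
        elif self.length is None and self.features:
            self.length = max(f.end for f in self.features)
        self.features.sort(key=lambda f: (f.start, f.end))
        if self.length is not None:
            for f in self.features:
                if f.start > self.length or f.end > self.length:
                    raise GenomeValidationError(
                        f"{f.name}: coordinates exceed genome length {self.length}"
                    )

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def features_of(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]


def feature_length(f: GeneFeature, genome_length: int, circular: bool = True) -> int:
    """Span of a feature in bp; origin-spanning intervals wrap."""
    if f.end >= f.start:
        return f.end - f.start + 1
    if not circular:
        raise GenomeValidationError(
            f"{f.name}: end < start requires a circular genome"
        )
    return (genome_length - f.start + 1) + f.end


def extract_feature_sequence(g: MitoGenome, f: GeneFeature) -> str:
    """Sense-strand (coding) sequence of a feature.

    H-strand features return the stored slice; L-strand features the
    reverse complement, so the result always reads 5'->3' in the gene's
    own frame.
    """
    if g.sequence is None:
        raise GenomeValidationError(f"genome {g.id} has no sequence")
    if f.end >= f.start:
        sub = g.sequence[f.start - 1 : f.end]
    else:
        if not g.circular:
            raise GenomeValidationError(f"{f.name}: wraps origin of a linear genome")
        sub = g.sequence[f.start - 1 :] + g.sequence[: f.end]
    return reverse_complement(sub) if f.strand == "L" else sub


def _strand_symbol(s: str) -> str:
    if s in ("+", "H"):
        return "H"
    if s in ("-", "L", "−"):  # accepts the typographic minus too
        return "L"
    raise GenomeValidationError(f"unknown strand symbol {s!r}")


def read_feature_table(
    path: str | Path, sequence: str | Path | None = None, id: str | None = None
) -> MitoGenome:
    """Read a TSV feature table (Gene/Start/End/Strand/Size/StartCodon/
    StopCodon/Anticodon). '-' cells mean absent; a Size column, if present,
    is validated against the coordinates."""
    path = Path(path)
    seq = None
    if sequence is not None:
        rec = next(SeqIO.parse(str(sequence), "fasta"))
        seq = str(rec.seq).upper()
    feats: list[GeneFeature] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "Gene" not in reader.fieldnames:
            raise GenomeValidationError(f"{path}: missing header with Gene column")
        for row in reader:
            name = row["Gene"].strip().strip("*")
            cat = categorize(name)
            if cat is None:
                norm = normalize_gene_name(name)
                if norm is None:
                    warnings.warn(f"unmappable gene name {name!r}; kept raw")
                    cat = "tRNA" if name.lower().startswith("trn") else "PCG"
                else:
                    name, cat = norm, categorize(norm)

            def cell(key):
                v = (row.get(key) or "").strip()
                return None if v in ("", "-", "−") else v

            f = GeneFeature(
                name=name,
                category=cat,
                start=int(row["Start"].replace(",", "")),
                end=int(row["End"].replace(",", "")),
                strand=_strand_symbol(row["Strand"].strip()),
                anticodon=cell("Anticodon"),
                start_codon=cell("StartCodon"),
                stop_codon=cell("StopCodon"),
            )
            feats.append(f)
    g = MitoGenome(id=id or path.stem, sequence=seq, features=feats)
    # Size validation needs the final genome length (wrap-aware).
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            size = (row.get("Size") or "").strip()
            if size in ("", "-", "−"):
                continue
            name = row["Gene"].strip().strip("*")
            norm = normalize_gene_name(name)
            name = norm if norm is not None else name
            f = g.feature(name)
            expect = feature_length(f, g.length, g.circular)
            if int(size.replace(",", "")) != expect:
                raise GenomeValidationError(
                    f"{name}: Size column {size} != computed size {expect}"
                )
    return g


def write_feature_table(g: MitoGenome, path: str | Path) -> None:
    """Write the TSV feature table; round-trips through read_feature_table."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["Gene", "Start", "End", "Strand", "Size", "StartCodon", "StopCodon",
             "Anticodon"]
        )
        for f in g.features:
            w.writerow(
                [
                    f.name,
                    f.start,
                    f.end,
                    "+" if f.strand == "H" else "-",
                    feature_length(f, g.length, g.circular),
                    f.start_codon or "-",
                    f.stop_codon or "-",
                    f.anticodon or "-",
                ]
            )


def write_fasta(g: MitoGenome, path: str | Path, width: int = 70) -> None:
    if g.sequence is None:
        raise GenomeValidationError("no sequence to write")
    with open(path, "w") as fh:
        header = f">{g.id}"
        if g.species:
            header += f" {g.species}"
        fh.write(header + "\n")
        for i in range(0, len(g.sequence), width):
            fh.write(g.sequence[i : i + width] + "\n")


_GENBANK_TYPES = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                  "D-loop": "control_region"}


def read_genbank(path: str | Path) -> list[MitoGenome]:
    """Read GenBank flat file(s); gene names are normalized to the package
    lexicon (ND1 -> nad1, COI -> cox1, D-loop -> CR, ...)."""
    genomes = []
    for rec in SeqIO.parse(str(path), "genbank"):
        feats: list[GeneFeature] = []
        for ft in rec.features:
            if ft.type not in _GENBANK_TYPES:
                continue
            raw = (
                ft.qualifiers.get("gene", [None])[0]
                or ft.qualifiers.get("product", [None])[0]
                or ft.type
            )
            name = normalize_gene_name(raw)
            if name is None:
                warnings.warn(f"unmappable gene name {raw!r}; kept raw")
                name = raw
                cat = _GENBANK_TYPES[ft.type]
            else:
                cat = categorize(name) or _GENBANK_TYPES[ft.type]
            strand = "L" if ft.location.strand == -1 else "H"
            feats.append(
                GeneFeature(
                    name=name,
                    category=cat,
                    start=int(ft.location.start) + 1,
                    end=int(ft.location.end),
                    strand=strand,
                    anticodon=ft.qualifiers.get("anticodon", [None])[0]
                    if cat == "tRNA"
                    else None,
                )
            )
        seq = str(rec.seq).upper() if len(rec.seq) else None
        genomes.append(
            MitoGenome(
                id=rec.id,
                species=rec.annotations.get("organism", ""),
                sequence=seq,
                length=len(rec.seq) or None,
                features=feats,
            )
        )
    return genomes


def reference_feature_table() -> MitoGenome:
    """The shipped M. kuntee 37-gene reference table (printed annotation)."""
    with importlib.resources.as_file(
        importlib.resources.files("mitochar.data").joinpath("mkuntee_features.tsv")
    ) as p:
        return read_feature_table(p, id="M_kuntee_ref")
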
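"""GenBank genome I/O and synthetic fixture genomes.

A :class:`GenomeRecord` is one annotated replicon: its DNA sequence, a
circularity flag and an ordered list of CDS features.  Coordinates are
0-based half-open throughout the package; GenBank's 1-based inclusive
convention is converted exactly once, at the parse boundary.

Origin-spanning CDS on circular replicons are "rotated out": the parser
rotates the sequence so that no feature crosses the origin and records the
rotation offset, which keeps all downstream window arithmetic linear.

Translation uses the bacterial/archaeal genetic code (translation table 11)
unconditionally; the package's domain is prokaryotes.

:func:`make_fixture_genome` builds deterministic synthetic genomes with
planted genes (orthologs, paralogs, fusions) whose translated-search hit
coordinates are exactly predictable: every planted CDS is guarded by
in-frame stop codons so a local alignment against the planted protein
cannot extend past the gene body.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, TextIO, Union

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_DNA_OK = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_TABLE11 = unambiguous_dna_by_id[11]


class GenBankParseError(ValueError):
    """Raised when a GenBank flat file cannot be parsed."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CDSFeature:
    """One protein-coding feature, 0-based half-open, strand +1/-1."""

    locus_tag: str
    product: str
    start: int
    end: int
    strand: int
    translation: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1 or -1, got {self.strand}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid CDS interval [{self.start}, {self.end})")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GenomeRecord:
    """One annotated replicon with features sorted by start coordinate."""

    accession: str
    organism_name: str
    sequence: str
    is_circular: bool = False
    features: list[CDSFeature] = field(default_factory=list)
    rotation_offset: int = 0

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _DNA_OK
        if bad:
            raise ValueError(
                f"{self.accession}: sequence contains characters outside A/C/G/T/N: "
                f"{sorted(bad)}"
            )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.end > self.length_bp:
                raise ValueError(
                    f"{self.accession}: feature {f.locus_tag} ends at {f.end} beyond "
                    f"sequence length {self.length_bp}"
                )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


def translate_cds(feature: CDSFeature, genome: GenomeRecord) -> str:
    """Translate a CDS under translation table 11.

    The minus strand is reverse-complemented first; a trailing stop is
    removed while internal stops are preserved (the annotation is treated
    as authoritative).  An interval that is not a multiple of three is
    translated codon by codon for floor(length/3) codons with a warning.
    """
    if feature.end - feature.start < 3:
        raise ValueError(
            f"CDS {feature.locus_tag} shorter than one codon: "
            f"[{feature.start}, {feature.end})"
        )
    dna = genome.sequence[feature.start : feature.end]
    if feature.strand == -1:
        dna = reverse_complement(dna)
    extra = len(dna) % 3
    if extra:
        logger.warning(
            "CDS %s length %d is not a multiple of 3; translating %d codons",
            feature.locus_tag,
            len(dna),
            len(dna) // 3,
        )
        dna = dna[: len(dna) - extra]
    prot = str(Seq(dna).translate(table=11))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


# ---------------------------------------------------------------------------
# parsing

def _as_handle(source: Union[str, Path, TextIO]) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    text = str(source)
    if "\n" in text or text.lstrip().startswith("LOCUS"):
        return io.StringIO(text)
    return open(text)


def _raw_features(rec: SeqRecord, length: int) -> list[dict]:
    out = []
    for f in rec.features:
        if f.type != "CDS":
            continue
        strand = f.location.strand if f.location.strand in (1, -1) else 1
        parts = sorted(f.location.parts, key=lambda p: int(p.start))
        start = int(parts[0].start)
        end = int(parts[-1].end)
        wraps = False
        if len(parts) == 2 and int(parts[-1].end) == length and int(parts[0].start) == 0:
            # join(x..L, 1..y): an origin-spanning CDS on a circular replicon
            wraps = True
            start = int(parts[1].start)
            end = int(parts[0].end)  # end measured past the origin
        quals = f.qualifiers
        out.append(
            {
                "locus_tag": quals.get("locus_tag", [""])[0],
                "product": quals.get("product", ["hypothetical protein"])[0],
                "start": start,
                "end": end,
                "strand": strand,
                "translation": quals.get("translation", [None])[0],
                "wraps": wraps,
            }
        )
    return out


def parse_genbank(source: Union[str, Path, TextIO]) -> list[GenomeRecord]:
    """Parse a GenBank flat file into one :class:`GenomeRecord` per LOCUS.

    CDS features lacking a /translation qualifier are translated here;
    join()/complement() locations are resolved to start/end/strand; CDS
    exceeding the sequence bounds are skipped with a warning.  Ambiguity
    codes other than N are rejected.
    """
    handle = _as_handle(source)
    try:
        seq_records = list(SeqIO.parse(handle, "genbank"))
    except ValueError as exc:
        raise GenBankParseError(f"malformed GenBank input: {exc}") from exc
    if not seq_records:
        raise GenBankParseError("no LOCUS entries found in GenBank input")
    records = []
    for rec in seq_records:
        seq = str(rec.seq).upper()
        length = len(seq)
        if length == 0:
            raise GenBankParseError(f"{rec.id}: missing ORIGIN sequence block")
        circular = rec.annotations.get("topology", "linear") == "circular"
        organism = rec.annotations.get("organism", rec.description or rec.id)
        raw = []
        for rf in _raw_features(rec, length):
            if rf["end"] > length and not rf["wraps"]:
                logger.warning(
                    "%s: CDS %s [%d, %d) exceeds sequence length %d; skipped",
                    rec.id,
                    rf["locus_tag"],
                    rf["start"],
                    rf["end"],
                    length,
                )
                continue
            raw.append(rf)
        offset = 0
        if circular and any(rf["wraps"] for rf in raw):
            offset, raw = _rotate_features(raw, length, rec.id)
            seq = seq[offset:] + seq[:offset]
        features = [
            CDSFeature(
                locus_tag=rf["locus_tag"],
                product=rf["product"],
                start=rf["start"],
                end=rf["end"],
                strand=rf["strand"],
                translation=rf["translation"],
            )
            for rf in raw
        ]
        genome = GenomeRecord(
            accession=rec.id.split(".")[0] or rec.name,
            organism_name=organism,
            sequence=seq,
            is_circular=circular,
            features=features,
            rotation_offset=offset,
        )
        genome.features = [
            f if f.translation else replace(f, translation=translate_cds(f, genome))
            for f in genome.features
        ]
        records.append(genome)
    return records


def _rotate_features(raw: list[dict], length: int, rec_id: str) -> tuple[int, list[dict]]:
    """Pick a rotation offset so no feature spans the origin; shift coordinates."""
    candidates = sorted(rf["start"] for rf in raw if rf["wraps"])
    for offset in candidates:
        shifted = []
        ok = True
        for rf in raw:
            span = (length - rf["start"] + rf["end"]) if rf["wraps"] else rf["end"] - rf["start"]
            new_start = (rf["start"] - offset) % length
            if new_start + span > length:
                ok = False
                break
            nf = dict(rf)
            nf["start"] = new_start
            nf["end"] = new_start + span
            nf["wraps"] = False
            shifted.append(nf)
        if ok:
            return offset, shifted
    raise GenBankParseError(
        f"{rec_id}: cannot rotate circular replicon to remove origin-spanning CDS"
    )


# ---------------------------------------------------------------------------
# writing

def write_genbank(records: Iterable[GenomeRecord]) -> str:
    """Serialize genome records as GenBank flat-file text (round-trip safe)."""
    out = []
    for g in records:
        rec = SeqRecord(
            Seq(g.sequence),
            id=g.accession,
            name=g.accession,
            description=g.organism_name,
            annotations={
                "molecule_type": "DNA",
                "topology": "circular" if g.is_circular else "linear",
                "organism": g.organism_name,
                "source": g.organism_name,
                "data_file_division": "BCT",
            },
        )
        rec.features.append(
            SeqFeature(
                SimpleLocation(0, g.length_bp, strand=1),
                type="source",
                qualifiers={"organism": [g.organism_name]},
            )
        )
        for f in g.features:
            quals = {
                "locus_tag": [f.locus_tag],
                "product": [f.product],
                "transl_table": ["11"],
            }
            if f.translation:
                quals["translation"] = [f.translation]
            rec.features.append(
                SeqFeature(
                    SimpleLocation(f.start, f.end, strand=f.strand),
                    type="CDS",
                    qualifiers=quals,
                )
            )
        out.append(rec)
    handle = io.StringIO()
    SeqIO.write(out, handle, "genbank")
    return handle.getvalue()


def write_cds_fasta(genome: GenomeRecord) -> str:
    """FASTA of the translated CDS proteins of one replicon."""
    lines = []
    for f in genome.features:
        prot = f.translation or translate_cds(f, genome)
        lines.append(f">{genome.accession}|{f.locus_tag} {f.product}")
        lines.extend(prot[i : i + 60] for i in range(0, len(prot), 60))
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# synthetic fixture genomes

AA20 = "ARNDCQEGHILKMFPSTWYV"

_BACK_TABLE: dict[str, list[str]] = {}
for _codon, _aa in sorted(_TABLE11.forward_table.items()):
    if set(_codon) <= set("ACGT"):
        _BACK_TABLE.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class PlantedGene:
    """A gene to plant in a fixture genome.

    ``start`` is the 0-based coordinate of the CDS (which includes a stop
    codon, so the CDS occupies ``3 * len(protein) + 3`` bp).  A fusion gene
    is simply a PlantedGene whose protein is the concatenation of two
    parent proteins.
    """

    locus_tag: str
    protein: str
    start: int
    strand: int = 1
    product: str = "hypothetical protein"

    @property
    def cds_length(self) -> int:
        return 3 * len(self.protein) + 3

    @property
    def end(self) -> int:
        return self.start + self.cds_length


@dataclass(frozen=True)
class FixtureSpec:
    """Blueprint for one synthetic replicon with planted genes."""

    accession: str
    organism: str
    length_bp: int
    genes: tuple[PlantedGene, ...] = ()
    circular: bool = False
    gc: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        spans = sorted((g.start, g.end, g.locus_tag) for g in self.genes)
        for (s1, e1, t1), (s2, e2, t2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"planted genes {t1} and {t2} overlap")
        for s, e, t in spans:
            if s < 3 or e + 3 > self.length_bp:
                raise ValueError(
                    f"planted gene {t} too close to the sequence boundary "
                    "(3 bp of guard space is required on each side)"
                )


def planted_hit_center(gene: PlantedGene) -> int:
    """Genomic center of the translated-search hit a planted gene produces."""
    coding = 3 * len(gene.protein)
    if gene.strand >= 0:
        return gene.start + coding // 2
    return gene.start + 3 + coding // 2


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def mutate_protein(rng: np.random.Generator, protein: str, identity: float) -> str:
    """Return a copy of ``protein`` with ~(1-identity) of positions substituted."""
    out = list(protein)
    for i in range(len(out)):
        if rng.random() > identity:
            choices = [a for a in AA20 if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _count_overlapping(haystack: str, needle: str) -> int:
    count = 0
    pos = haystack.find(needle)
    while pos != -1:
        count += 1
        pos = haystack.find(needle, pos + 1)
    return count


def _six_frame(seq: str) -> list[str]:
    frames = []
    for s in (seq, reverse_complement(seq)):
        for f in range(3):
            sub = s[f : f + 3 * ((len(s) - f) // 3)]
            frames.append(str(Seq(sub).translate(table=11)))
    return frames


def make_fixture_genome(
    spec: FixtureSpec, seed: int
) -> tuple[GenomeRecord, str]:
    """Build a deterministic synthetic replicon and its GenBank text.

    The intergenic background is random sequence with the requested GC
    fraction, verified to contain no 30-mer of any planted protein in any
    reading frame outside the planted CDS; each CDS is flanked by in-frame
    stop codons so planted proteins are exactly recoverable and their
    translated-search hit coordinates are exact.  Identical spec + seed
    gives byte-identical GenBank output.
    """
    expected: dict[str, int] = {}
    for g in spec.genes:
        windows = (
            [g.protein]
            if len(g.protein) <= 30
            else [g.protein[i : i + 30] for i in range(len(g.protein) - 29)]
        )
        for w in windows:
            expected[w] = sum(_count_overlapping(h.protein, w) for h in spec.genes)

    for attempt in range(20):
        rng = np.random.default_rng([seed, attempt])
        p_at = (1.0 - spec.gc) / 2.0
        p_gc = spec.gc / 2.0
        seq = rng.choice(list("ACGT"), size=spec.length_bp, p=[p_at, p_gc, p_gc, p_at])
        seq = list("".join(seq))
        for g in sorted(spec.genes, key=lambda x: x.start):
            codons = [
                _BACK_TABLE[aa][rng.integers(len(_BACK_TABLE[aa]))] for aa in g.protein
            ]
            dna = "".join(codons) + "TAA"
            guard5, guard3 = "TAA", "TAA"
            if g.strand == -1:
                dna = reverse_complement(dna)
                guard5, guard3 = reverse_complement("TAA"), reverse_complement("TAA")
            seq[g.start : g.end] = dna
            seq[g.start - 3 : g.start] = guard5
            seq[g.end : g.end + 3] = guard3
        text = "".join(seq)
        frames = _six_frame(text)
        ok = all(
            sum(_count_overlapping(fr, w) for fr in frames) <= n
            for w, n in expected.items()
        )
        if ok:
            break
    else:  # pragma: no cover - vanishingly unlikely for realistic specs
        raise RuntimeError(
            f"{spec.accession}: could not generate background free of "
            "planted-protein 30-mers in 20 attempts"
        )

    features = [
        CDSFeature(
            locus_tag=g.locus_tag,
            product=g.product,
            start=g.start,
            end=g.end,
            strand=g.strand,
            translation=g.protein,
        )
        for g in sorted(spec.genes, key=lambda x: x.start)
    ]
    record = GenomeRecord(
        accession=spec.accession,
        organism_name=spec.organism,
        sequence=text,
        is_circular=spec.circular,
        features=features,
    )
    return record, write_genbank([record])
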
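"""Domain annotation parsing, fragment merging and SM-class calling.

Domain scanners (InterProScan and friends) frequently report one catalytic
domain of a megasynthetase as several short, nearby fragments.  Before any
architecture call or sequence extraction, same-type fragments that are short
(< 350 aa) and close together (< 100 aa apart) are merged into one spanning
interval; the thresholds live in :class:`MergeConfig`.

Architecture calling is rule based: a PKS module is a ketosynthase (KS) plus
an acyltransferase (AT); an NRPS module is a condensation (C) plus an
adenylation (A) domain.  A gene carrying both modules is a hybrid, oriented
P-type (PKS-NRPS) when the first KS precedes the first A domain along the
protein and N-type (NRPS-PKS) otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: controlled vocabulary for domain types
DOMAIN_TOKENS = frozenset(
    {"KS", "AT", "DH", "MT", "ER", "KR", "ACP", "C", "A", "T", "TE", "R", "other"}
)

#: SM gene classes produced by :func:`classify_architecture`
SM_CLASSES = (
    "PKS",
    "PKS-like",
    "NRPS",
    "NRPS-like",
    "PKS-NRPS",
    "NRPS-PKS",
    "hybrid-other",
    "other",
)


class DomainInputError(ValueError):
    """Raised for inconsistent or malformed domain annotation input."""


@dataclass(frozen=True)
class DomainAnnotation:
    """One typed interval on a protein, 1-based inclusive coordinates.

    ``source`` and ``merged_overlap`` are provenance, not identity: two
    annotations with the same gene, type and coordinates compare equal.
    ``merged_overlap`` flags intervals produced by merging overlapping
    same-type input rows (normally a scanner artifact).
    """

    gene_id: str
    domain_type: str
    start: int
    end: int
    source: str = field(default="", compare=False)
    merged_overlap: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise DomainInputError(
                f"invalid interval [{self.start},{self.end}] for "
                f"{self.gene_id}/{self.domain_type}"
            )
        if self.domain_type not in DOMAIN_TOKENS:
            raise DomainInputError(
                f"unknown domain type {self.domain_type!r}; "
                f"map it through the vocabulary first"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MergeConfig:
    """Thresholds for fragment merging.

    Two adjacent same-type annotations merge when both are shorter than
    ``max_fragment_len`` (350 aa) and the gap between them is below
    ``max_gap`` (100 aa).  A full-length domain is not a fragment, so the
    length condition applies to both candidates, never the merged span.
    """

    max_fragment_len: int = 350
    max_gap: int = 100


@dataclass(frozen=True)
class GeneArchitecture:
    gene_id: str
    species: str
    ordered_domains: tuple[DomainAnnotation, ...]
    sm_class: str
    orientation: str  # "P-type" | "N-type" | "none"

    @property
    def domain_string(self) -> str:
        return "-".join(d.domain_type for d in self.ordered_domains)


@dataclass(frozen=True)
class DomainSequence:
    gene_id: str
    domain_type: str
    sequence: str
    start: int
    end: int
    seq_id: str


def merge_domains(
    domains: Sequence[DomainAnnotation], config: MergeConfig | None = None
) -> list[DomainAnnotation]:
    """Merge fragmented same-type annotations of one gene to a fixed point.

    Adjacent (by start) same-type intervals merge when both lengths are
    below ``config.max_fragment_len`` and their gap (``next.start −
    prev.end − 1``) is below ``config.max_gap``.  Overlapping same-type
    intervals (negative gap) merge unconditionally and the result carries
    ``merged_overlap=True``.  Different types never merge.  The scan repeats
    until nothing changes; output is sorted by (start, end, type).
    """
    config = config or MergeConfig()
    if not domains:
        return []
    gene_ids = {d.gene_id for d in domains}
    if len(gene_ids) > 1:
        raise DomainInputError(f"mixed gene ids in merge input: {sorted(gene_ids)}")

    by_type: dict[str, list[DomainAnnotation]] = {}
    for d in domains:
        by_type.setdefault(d.domain_type, []).append(d)

    merged: list[DomainAnnotation] = []
    for dtype, group in by_type.items():
        group = sorted(group, key=lambda d: (d.start, d.end))
        # leftmost-first absorption: the current interval keeps absorbing its
        # successor while the rule allows; growth can only disable later
        # merges, never enable earlier ones, so one sweep reaches the fixed
        # point (the outer loop guards the invariant anyway)
        changed = True
        while changed:
            changed = False
            out: list[DomainAnnotation] = []
            cur = group[0]
            for nxt in group[1:]:
                gap = nxt.start - cur.end - 1
                overlap = gap < 0
                mergeable = overlap or (
                    cur.length < config.max_fragment_len
                    and nxt.length < config.max_fragment_len
                    and gap < config.max_gap
                )
                if mergeable:
                    cur = replace(
                        cur,
                        end=max(cur.end, nxt.end),
                        source=_join_sources(cur, nxt),
                        merged_overlap=cur.merged_overlap
                        or nxt.merged_overlap
                        or overlap,
                    )
                    changed = True
                else:
                    out.append(cur)
                    cur = nxt
            out.append(cur)
            group = out
            if len(group) == 1:
                break
        merged.extend(group)
    merged.sort(key=lambda d: (d.start, d.end, d.domain_type))
    return merged


def _join_sources(a: DomainAnnotation, b: DomainAnnotation) -> str:
    parts = [s for s in (a.source, b.source) if s]
    seen: list[str] = []
    for p in parts:
        if p not in seen:
            seen.append(p)
    return ";".join(seen)


def classify_architecture(
    domains: Sequence[DomainAnnotation],
    gene_id: str | None = None,
    species: str = "",
) -> GeneArchitecture:
    """Call the SM class and hybrid orientation of one merged gene.

    Expects merged annotations of a single gene.  Classification depends
    only on the sorted-by-start domain order, never on input order.
    """
    ordered = tuple(sorted(domains, key=lambda d: (d.start, d.end, d.domain_type)))
    if gene_id is None:
        gene_id = ordered[0].gene_id if ordered else ""
    types = {d.domain_type for d in ordered}

    pks_module = "KS" in types and "AT" in types
    nrps_module = "C" in types and "A" in types
    orientation = "none"
    if pks_module and nrps_module:
        first_ks = min(d.start for d in ordered if d.domain_type == "KS")
        first_a = min(d.start for d in ordered if d.domain_type == "A")
        if first_ks < first_a:
            sm_class, orientation = "PKS-NRPS", "P-type"
        else:
            sm_class, orientation = "NRPS-PKS", "N-type"
    elif pks_module:
        sm_class = "PKS"
    elif nrps_module:
        sm_class = "NRPS"
    elif "KS" in types:
        sm_class = "PKS-like"
    elif "A" in types:
        sm_class = "NRPS-like"
    else:
        sm_class = "other"
    return GeneArchitecture(
        gene_id=gene_id,
        species=species,
        ordered_domains=ordered,
        sm_class=sm_class,
        orientation=orientation,
    )


def extract_domain_sequences(
    arch: GeneArchitecture,
    protein: str,
    wanted: Iterable[str],
) -> list[DomainSequence]:
    """Slice the wanted merged domains out of the parent protein.

    Identifiers are ``<gene>_<type><ordinal>`` with ordinals counted per
    type in gene order, so two A domains of one gene become ``_A1`` and
    ``_A2``.
    """
    wanted = set(wanted)
    out: list[DomainSequence] = []
    counters: dict[str, int] = {}
    for d in arch.ordered_domains:
        if d.domain_type not in wanted:
            continue
        if d.end > len(protein):
            raise DomainInputError(
                f"domain {d.domain_type}[{d.start},{d.end}] of {arch.gene_id} "
                f"extends past protein end ({len(protein)} aa)"
            )
        n = counters.get(d.domain_type, 0) + 1
        counters[d.domain_type] = n
        out.append(
            DomainSequence(
                gene_id=arch.gene_id,
                domain_type=d.domain_type,
                sequence=protein[d.start - 1 : d.end],
                start=d.start,
                end=d.end,
                seq_id=f"{arch.gene_id}_{d.domain_type}{n}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# vocabulary and file I/O
# ---------------------------------------------------------------------------

_DEFAULT_VOCAB = Path(__file__).parent / "data" / "domain_vocab.tsv"


def load_vocabulary(path: str | Path | None = None) -> dict[str, str]:
    """Load the signature-accession -> domain-token mapping (TSV, 2 columns).

    The packaged default covers the common Pfam signatures of PKS/NRPS
    catalytic domains; it is a plain editable table, pass your own to
    override.  Identity rows for the tokens themselves are always included
    so pre-tokenized input passes through.
    """
    vocab = {t: t for t in DOMAIN_TOKENS}
    p = Path(path) if path is not None else _DEFAULT_VOCAB
    with open(p) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DomainInputError(f"vocabulary line needs 2 columns: {line!r}")
            acc, token = fields[0], fields[1]
            if token not in DOMAIN_TOKENS:
                raise DomainInputError(f"vocabulary maps {acc} to unknown token {token!r}")
            vocab[acc] = token
    return vocab


def read_interproscan_tsv(
    path: str | Path,
    vocab: Mapping[str, str] | None = None,
    keep_other: bool = False,
) -> dict[str, list[DomainAnnotation]]:
    """Read an InterProScan 5 TSV into per-gene annotation lists.

    Only the protein accession (col 1), signature accession (col 5) and
    start/stop (cols 7/8) are consumed.  Signatures missing from the
    vocabulary map to ``other`` and are dropped unless ``keep_other``.
    Duplicate (gene, type, start) rows are rejected: they would make
    downstream orientation calls ambiguous.
    """
    vocab = vocab or load_vocabulary()
    per_gene: dict[str, list[DomainAnnotation]] = {}
    seen: set[tuple[str, str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise DomainInputError(
                    f"{path}:{lineno}: expected >= 8 tab-separated columns"
                )
            gene, sig = fields[0], fields[4]
            try:
                start, end = int(fields[6]), int(fields[7])
            except ValueError as exc:
                raise DomainInputError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            token = vocab.get(sig, "other")
            if token == "other" and not keep_other:
                continue
            key = (gene, token, start)
            if key in seen:
                raise DomainInputError(
                    f"{path}:{lineno}: duplicate ({token},{start}) row for {gene}"
                )
            seen.add(key)
            per_gene.setdefault(gene, []).append(
                DomainAnnotation(gene, token, start, end, source=fields[3] if len(fields) > 3 else "")
            )
    return per_gene


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_domain_fasta(seqs: Iterable[DomainSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.seq_id,
                  description=f"{s.gene_id} {s.domain_type} {s.start}-{s.end}")
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


_ARCH_HEADER = ["gene_id", "species", "sm_class", "orientation", "domain_string", "domain_coords"]


def write_architecture_table(
    archs: Iterable[GeneArchitecture], path: str | Path
) -> None:
    """Write architecture calls as TSV; ``domain_coords`` keeps the merged
    intervals (``type:start-end;...``) so the table round-trips exactly."""
    with open(path, "w") as fh:
        fh.write("\t".join(_ARCH_HEADER) + "\n")
        for a in archs:
            coords = ";".join(
                f"{d.domain_type}:{d.start}-{d.end}" for d in a.ordered_domains
            )
            fh.write(
                "\t".join([a.gene_id, a.species, a.sm_class, a.orientation,
                           a.domain_string, coords]) + "\n"
            )


def read_architecture_table(path: str | Path) -> list[GeneArchitecture]:
    out: list[GeneArchitecture] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ARCH_HEADER:
            raise DomainInputError(f"unexpected architecture table header in {path}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene, species, sm_class, orientation, _dstring, coords = line.split("\t")
            domains = []
            if coords:
                for item in coords.split(";"):
                    dtype, span = item.split(":")
                    s, e = span.split("-")
                    domains.append(DomainAnnotation(gene, dtype, int(s), int(e)))
            out.append(
                GeneArchitecture(gene, species, tuple(domains), sm_class, orientation)
            )
    return out


def classify_table(
    per_gene: Mapping[str, list[DomainAnnotation]],
    species_of: Mapping[str, str] | None = None,
    config: MergeConfig | None = None,
) -> list[GeneArchitecture]:
    """Merge and classify every gene of a parsed annotation table."""
    species_of = species_of or {}
    archs = []
    for gene in sorted(per_gene):
        merged = merge_domains(per_gene[gene], config)
        if any(d.merged_overlap for d in merged):
            warnings.warn(
                f"{gene}: overlapping same-type annotations merged", stacklevel=2
            )
        archs.append(
            classify_architecture(merged, gene_id=gene, species=species_of.get(gene, ""))
        )
    return archs
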
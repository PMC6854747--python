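"""End-to-end orchestration: classify -> extract -> distances -> nn-origin ->
monophyly -> summaries, with a reproducibility manifest.

Tree building (alignment, trimming, ML inference) is external by contract:
the pipeline consumes a Newick gene tree.  Every stage writes its artifact
into the output directory and the manifest records inputs, parameters and
SHA-256 checksums, so deterministic stages are byte-stable across reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

from hybridtrace import __version__, clade_analysis, domain_architecture as da
from hybridtrace import phylo_distance as pdist
from hybridtrace import tree_io

log = logging.getLogger("hybridtrace")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


@dataclass
class RunConfig:
    tree: str | Path | None = None
    meta: str | Path | None = None
    domains: str | Path | None = None
    fasta: str | Path | None = None
    vocab: str | Path | None = None
    outdir: str | Path = "hybridtrace_out"
    extract_types: tuple[str, ...] = ("KS", "A")
    #: metadata filters selecting focal tips, e.g. {"sm_class": {"PKS-NRPS", "NRPS-PKS"}}
    focal: dict = field(default_factory=dict)
    #: metadata attribute whose values are each tested for monophyly
    monophyly_attribute: str = "section"
    hgt_quantile: float = 0.25
    max_fragment_len: int = 350
    max_gap: int = 100
    seed: int = 0

    @classmethod
    def toy(cls, outdir: str | Path) -> "RunConfig":
        """Configuration for the bundled 12-gene, 6-species, 2-section toy
        dataset with one planted cross-section transfer."""
        toy = resources.files("hybridtrace") / "data" / "toy"
        return cls(
            tree=str(toy / "gene_tree.nwk"),
            meta=str(toy / "meta.tsv"),
            domains=str(toy / "domains.tsv"),
            fasta=str(toy / "proteins.faa"),
            outdir=outdir,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all applicable stages; return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stages: list[dict] = []

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            stages.append({"name": name, "seconds": round(time.perf_counter() - t0, 4)})
            log.info("stage %s done in %.3fs", name, stages[-1]["seconds"])
        return wrap

    archs: list = []
    if config.domains:
        def _classify():
            vocab = da.load_vocabulary(config.vocab)
            per_gene = da.read_interproscan_tsv(config.domains, vocab)
            meta = tree_io.load_tip_metadata(config.meta) if config.meta else None
            species_of = dict(meta["species"]) if meta is not None else {}
            mc = da.MergeConfig(config.max_fragment_len, config.max_gap)
            archs.extend(da.classify_table(per_gene, species_of, mc))
            p = outdir / "architectures.tsv"
            da.write_architecture_table(archs, p)
            artifacts.append(p)
        stage("classify")(_classify)

    if config.domains and config.fasta:
        def _extract():
            proteins = da.read_fasta(config.fasta)
            seqs = []
            for a in archs:
                if a.gene_id not in proteins:
                    raise PipelineError(f"no protein sequence for {a.gene_id}")
                seqs.extend(
                    da.extract_domain_sequences(
                        a, proteins[a.gene_id], config.extract_types
                    )
                )
            p = outdir / "extracted_domains.faa"
            da.write_domain_fasta(seqs, p)
            artifacts.append(p)
        stage("extract")(_extract)

    if config.tree:
        tree = tree_io.read_newick(config.tree)
        if config.meta is None:
            raise PipelineError("stage 'cophenetic' failed: tree analysis needs --meta")
        meta = tree_io.load_tip_metadata(config.meta)
        tree_io.validate_tip_metadata(tree, meta)

        dm_holder: dict = {}

        def _cophenetic():
            dm_holder["dm"] = pdist.cophenetic_matrix(tree)
            p = outdir / "distance_matrix.tsv"
            dm_holder["dm"].write_tsv(p)
            artifacts.append(p)
        stage("cophenetic")(_cophenetic)

        def _nn_origin():
            dm = dm_holder["dm"]
            focal = pdist.select_tips(meta, **config.focal) if config.focal else None
            nn = pdist.nearest_neighbor_origin(dm, meta, focal)
            nn = pdist.flag_candidate_hgt(nn, config.hgt_quantile)
            p = outdir / "nearest_neighbors.tsv"
            nn.to_csv(p, sep="\t", index=False)
            artifacts.append(p)
            summary = pdist.section_origin_summary(nn, meta)
            p = outdir / "section_origin_summary.tsv"
            summary.to_csv(p, sep="\t", index=False)
            artifacts.append(p)
        stage("nn-origin")(_nn_origin)

        def _monophyly():
            attr = config.monophyly_attribute
            rows = []
            tips_in_tree = set(tree_io.tip_labels(tree))
            for value in sorted(meta[attr].unique()):
                labeled = {
                    t for t in meta.index[meta[attr] == value] if t in tips_in_tree
                }
                if not labeled or labeled == tips_in_tree:
                    continue
                res = clade_analysis.is_monophyletic(tree, labeled)
                rows.append(
                    f"{attr}={value}\t{res.is_monophyletic}\t"
                    f"{','.join(res.intruding_tips or ())}"
                )
            p = outdir / "monophyly.tsv"
            p.write_text(
                "label_set\tis_monophyletic\tintruding_tips\n"
                + "".join(r + "\n" for r in rows)
            )
            artifacts.append(p)
        stage("monophyly")(_monophyly)

        def _paralogs():
            pp = clade_analysis.paralog_distances(dm_holder["dm"], meta)
            p = outdir / "paralog_distances.tsv"
            pp.to_csv(p, sep="\t", index=False)
            artifacts.append(p)
        stage("paralogs")(_paralogs)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else sorted(v) if isinstance(v, set) else v)
            for k, v in asdict(config).items()
            if k not in ("focal",)
        },
        "focal": {k: sorted(v) if not isinstance(v, str) else v
                  for k, v in config.focal.items()},
        "inputs": {
            k: str(getattr(config, k))
            for k in ("tree", "meta", "domains", "fasta", "vocab")
            if getattr(config, k)
        },
        "stages": stages,
        "artifacts": {str(p.name): _sha256(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
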
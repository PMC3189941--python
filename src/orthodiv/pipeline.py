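"""Stage orchestration: simulate -> orthologs -> annotate -> divergence -> kaks.

Each stage is a plain function over the library types; ``run_all`` chains
them, writes the versioned TSV reports and records a JSON manifest with
input hashes, parameters and the counts entering and leaving every filter
(the putative-pairs -> shared-protein-pairs -> CDS-filtered-pairs funnel).
All stages are deterministic given the configuration seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .align import AlignmentParams, ProteinSearchParams
from .annotate import AnnotateParams, AnnotatedOrtholog, Rejection, extract_regions
from .divergence import DivergenceTable, classify_sites, fold_ratios
from .io import as_seq_dict, read_fasta
from .orthologs import OrthologPair, RbhParams, paralog_filter, reciprocal_best_hits
from .selection import SelectionSummary, classify_selection, yn
from .simulate import SimulationConfig, simulate_transcriptomes, write_fixture

log = logging.getLogger("orthodiv")

REPORT_SCHEMAS = {
    "ortholog_pairs.tsv": ["id_a", "id_b", "score_ab", "score_ba", "n_columns",
                           "pair_identity", "shared_protein_id"],
    "divergence_table.tsv": ["group", "stratum", "pct_diff", "mean_loci", "se",
                             "compared_kb", "ts_tv", "n_subs", "n_ts", "n_tv",
                             "n_sites", "gc_pct", "cpg_pct", "loci"],
    "ratios.tsv": ["ratio", "value"],
    "kaks_table.tsv": ["pair_id", "method", "n_codons", "s_sites", "n_sites",
                       "s_sub", "n_sub", "ka", "ks", "ka_ks", "kappa_hat",
                       "selection_class"],
    "scatter.tsv": ["pair_id", "ka", "ks"],
}


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths for one run."""
    out_dir: str = "orthodiv_out"
    seed: int = 0
    species_a: str | None = None      # FASTA paths; None -> simulate stage provides
    species_b: str | None = None
    proteins: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    rbh: RbhParams = field(default_factory=RbhParams)
    protein_search: ProteinSearchParams = field(default_factory=ProteinSearchParams)
    annotate: AnnotateParams = field(default_factory=AnnotateParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, sub_cls in (("simulation", SimulationConfig),
                             ("alignment", AlignmentParams),
                             ("rbh", RbhParams),
                             ("protein_search", ProteinSearchParams)):
            if key in raw:
                sub = dict(raw.pop(key))
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                kwargs[key] = sub_cls(**sub)
        if "annotate" in raw:
            sub = dict(raw.pop("annotate"))
            kwargs["annotate"] = AnnotateParams(**sub)
        kwargs.update(raw)
        cfg = cls(**kwargs)
        cfg.simulation = dataclass_replace_seed(cfg.simulation, cfg.seed)
        return cfg

    def manifest_params(self) -> dict:
        d = {"out_dir": self.out_dir, "seed": self.seed,
             "species_a": self.species_a, "species_b": self.species_b,
             "proteins": self.proteins}
        for key in ("simulation", "alignment", "rbh", "protein_search"):
            d[key] = asdict(getattr(self, key))
        ann = asdict(self.annotate)
        d["annotate"] = ann
        return d


def dataclass_replace_seed(sim: SimulationConfig, seed: int) -> SimulationConfig:
    from dataclasses import replace
    return replace(sim, seed=seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Manifest:
    """Accumulates per-stage records; written as manifest.json."""

    def __init__(self, config: PipelineConfig):
        self.data = {"parameters": config.manifest_params(), "stages": []}

    def record(self, stage: str, inputs: list[Path], counts: dict, seconds: float):
        self.data["stages"].append({
            "stage": stage,
            "inputs": {str(p): _sha256(Path(p)) for p in inputs},
            "counts": counts,
            "seconds": round(seconds, 3),
        })

    def write(self, out_dir: Path):
        (out_dir / "manifest.json").write_text(
            json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def stage_simulate(config: PipelineConfig, manifest: Manifest | None = None) -> dict:
    t0 = time.perf_counter()
    world = simulate_transcriptomes(config.simulation)
    out = Path(config.out_dir)
    paths = write_fixture(world, out)
    counts = {"transcripts_a": len(world.records_a),
              "transcripts_b": len(world.records_b),
              "proteins": len(world.proteins)}
    log.info("simulate: %s", counts)
    if manifest is not None:
        manifest.record("simulate", [], counts, time.perf_counter() - t0)
    return {"world": world, "paths": paths}


def stage_orthologs(seqs_a, seqs_b, proteins: dict[str, str],
                    config: PipelineConfig, out_dir: Path,
                    manifest: Manifest | None = None,
                    input_paths: list[Path] = ()) -> list[OrthologPair]:
    t0 = time.perf_counter()
    putative = reciprocal_best_hits(seqs_a, seqs_b, config.alignment, config.rbh)
    pairs = paralog_filter(putative, seqs_a, seqs_b, proteins,
                           config.protein_search)
    counts = {"putative_rbh_pairs": len(putative),
              "shared_protein_pairs": len(pairs)}
    log.info("orthologs: %s", counts)
    _write_pairs(pairs, out_dir / "ortholog_pairs.tsv")
    if manifest is not None:
        manifest.record("orthologs", list(input_paths), counts,
                        time.perf_counter() - t0)
    return pairs


def _write_pairs(pairs: list[OrthologPair], path: Path) -> None:
    rows = [{"id_a": p.id_a, "id_b": p.id_b, "score_ab": p.hit_ab.score,
             "score_ba": p.hit_ba.score, "n_columns": p.hit_ab.n_columns,
             "pair_identity": p.pair_identity,
             "shared_protein_id": p.shared_protein_id or ""}
            for p in pairs]
    pd.DataFrame(rows, columns=REPORT_SCHEMAS["ortholog_pairs.tsv"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def stage_annotate(pairs: list[OrthologPair], seqs_a, seqs_b,
                   proteins: dict[str, str], config: PipelineConfig,
                   out_dir: Path, manifest: Manifest | None = None
                   ) -> tuple[list[AnnotatedOrtholog], list[Rejection]]:
    t0 = time.perf_counter()
    accepted: list[AnnotatedOrtholog] = []
    rejected: list[Rejection] = []
    for pair in pairs:
        if not pair.shared_protein_id:
            rejected.append(Rejection(pair, "no_shared_protein"))
            continue
        result = extract_regions(pair, seqs_a, seqs_b,
                                 proteins[pair.shared_protein_id],
                                 config.annotate)
        (accepted if isinstance(result, AnnotatedOrtholog) else rejected).append(result)  # type: ignore[arg-type]
    counts = {
        "pairs_in": len(pairs),
        "cds_filtered_pairs": len(accepted),
        "with_utr5": sum(1 for a in accepted
                         if any(r.label == "utr5" for r in a.regions)),
        "with_utr3": sum(1 for a in accepted
                         if any(r.label == "utr3" for r in a.regions)),
        "rejections": _rejection_counts(rejected),
    }
    log.info("annotate: %s", counts)
    _write_annotations(accepted, rejected, out_dir)
    if manifest is not None:
        manifest.record("annotate", [], counts, time.perf_counter() - t0)
    return accepted, rejected


def _rejection_counts(rejected: list[Rejection]) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in rejected:
        out[r.reason] = out.get(r.reason, 0) + 1
    return dict(sorted(out.items()))


def _write_annotations(accepted, rejected, out_dir: Path) -> None:
    rows = []
    for a in accepted:
        for mem, tag in ((a.member_a, "a"), (a.member_b, "b")):
            rows.append({
                "pair_id": a.pair.id_a, "member": tag,
                "transcript_id": mem.transcript_id, "strand": mem.strand,
                "cds_start": mem.cds[0], "cds_end": mem.cds[1],
                "utr5_start": mem.utr5[0] if mem.utr5 else "",
                "utr5_end": mem.utr5[1] if mem.utr5 else "",
                "utr3_start": mem.utr3[0] if mem.utr3 else "",
                "utr3_end": mem.utr3[1] if mem.utr3 else "",
                "start_codon_found": mem.start_found,
                "stop_codon_found": mem.stop_found,
            })
    pd.DataFrame(rows).to_csv(out_dir / "annotations.tsv", sep="\t", index=False)
    rej = [{"id_a": r.pair.id_a, "id_b": r.pair.id_b, "reason": r.reason}
           for r in rejected]
    pd.DataFrame(rej, columns=["id_a", "id_b", "reason"]).to_csv(
        out_dir / "rejections.tsv", sep="\t", index=False)


def stage_divergence(annotated: list[AnnotatedOrtholog], out_dir: Path,
                     manifest: Manifest | None = None,
                     cpg_mode: str = "either") -> DivergenceTable:
    t0 = time.perf_counter()
    sites = pd.concat([classify_sites(a, cpg_mode) for a in annotated],
                      ignore_index=True) if annotated else None
    if sites is None or sites.empty:
        raise ValueError("no annotated pairs to compare")
    table = DivergenceTable.from_sites(sites)
    table.to_tsv(out_dir / "divergence_table.tsv")
    ratios = fold_ratios(table)
    pd.DataFrame([{"ratio": k, "value": v} for k, v in ratios.items()]).to_csv(
        out_dir / "ratios.tsv", sep="\t", index=False, float_format="%.6g")
    counts = {"loci": int(sites["pair_id"].nunique()),
              "compared_sites": int(len(sites))}
    log.info("divergence: %s", counts)
    if manifest is not None:
        manifest.record("divergence", [], counts, time.perf_counter() - t0)
    return table


def stage_kaks(annotated: list[AnnotatedOrtholog], out_dir: Path,
               manifest: Manifest | None = None) -> SelectionSummary:
    t0 = time.perf_counter()
    results = []
    for a in annotated:
        cds_a, cds_b = a.aligned_cds
        results.append(yn(cds_a, cds_b, pair_id=a.pair.id_a))
    summary = classify_selection(results)
    summary.table.to_csv(out_dir / "kaks_table.tsv", sep="\t", index=False,
                         float_format="%.6g")
    summary.scatter.to_csv(out_dir / "scatter.tsv", sep="\t", index=False,
                           float_format="%.6g")
    counts = {"pairs_in": summary.n_total,
              "with_both_rates": summary.n_with_both_rates,
              "positive": len(summary.bands["positive"]),
              "relaxed": len(summary.bands["relaxed"]),
              "constrained": len(summary.bands["constrained"])}
    log.info("kaks: %s", counts)
    if manifest is not None:
        manifest.record("kaks", [], counts, time.perf_counter() - t0)
    return summary


@dataclass
class PipelineResult:
    pairs: list[OrthologPair]
    annotated: list[AnnotatedOrtholog]
    rejected: list[Rejection]
    divergence: DivergenceTable
    selection: SelectionSummary
    manifest: Manifest


def run_all(config: PipelineConfig) -> PipelineResult:
    """Full pipeline; simulates a fixture when no input FASTAs are given."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config)
    input_paths: list[Path] = []
    if config.species_a and config.species_b and config.proteins:
        seqs_a = as_seq_dict(read_fasta(config.species_a, "A"))
        seqs_b = as_seq_dict(read_fasta(config.species_b, "B"))
        proteins = as_seq_dict(read_fasta(config.proteins, "protein"))
        input_paths = [Path(config.species_a), Path(config.species_b),
                       Path(config.proteins)]
    else:
        sim = stage_simulate(config, manifest)
        world = sim["world"]
        seqs_a, seqs_b = as_seq_dict(world.records_a), as_seq_dict(world.records_b)
        proteins = world.proteins
        input_paths = list(sim["paths"].values())
    pairs = stage_orthologs(seqs_a, seqs_b, proteins, config, out_dir,
                            manifest, input_paths)
    annotated, rejected = stage_annotate(pairs, seqs_a, seqs_b, proteins,
                                         config, out_dir, manifest)
    table = stage_divergence(annotated, out_dir, manifest)
    summary = stage_kaks(annotated, out_dir, manifest)
    manifest.write(out_dir)
    return PipelineResult(pairs, annotated, rejected, table, summary, manifest)
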
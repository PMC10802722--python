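"""End-to-end orchestration: preprocess -> call -> dedup -> annotate -> report.

The object-level entry point is :func:`run_from_objects`, which the file-based
:func:`run_pipeline` wraps with config loading and TSV/JSON output. Filter
order is fixed (hop -> PhiX -> merge -> quality) and every stage's
kept + discarded equals its input, which the discard log records per read.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

import breakins
from breakins.annotate import annotate_sources, junction_profile, nucleotide_frequency, ty1_realign
from breakins.call import (
    InsertionEvent,
    call_merged,
    call_unmerged,
    locus_intervals_of_read,
    segment_donors,
)
from breakins.dedup import DedupThresholds, InsertionCluster, dedup_events
from breakins.model import AmpliconDesign, ReferenceGenome, load_features, load_reference, revcomp
from breakins.preprocess import (
    DiscardLog,
    demultiplex_and_filter_hops,
    filter_phix,
    merge_pairs,
    quality_filter,
)
from breakins.stats import eligible_territory, fold_change_report, permutation_test

log = logging.getLogger(__name__)


@dataclass
class RawPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    illumina_pair: tuple[str, str]


@dataclass
class StageCounts:
    input_pairs: int = 0
    demux_kept: int = 0
    demux_discarded: int = 0
    phix_removed: int = 0
    merged: int = 0
    unmerged: int = 0
    quality_dropped: int = 0
    called_events: int = 0
    candidate_events: int = 0
    unique_insertions: int = 0
    contaminants: int = 0

    def conserved(self) -> bool:
        return self.input_pairs == self.demux_kept + self.demux_discarded


@dataclass
class PipelineResult:
    clusters: list[InsertionCluster]
    contaminants: list[InsertionCluster]
    candidate_events: list[InsertionEvent]
    call_reasons: dict[str, int]
    discard_log: DiscardLog
    counts: StageCounts


def run_from_objects(
    raw_pairs,
    genome: ReferenceGenome,
    design: AmpliconDesign,
    decoy_seq: str,
    batch_map: dict[str, str] | None = None,
    thresholds: DedupThresholds | None = None,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
    phix_k: int = 31,
    q_locus: float = 25.0,
    q_rest: float = 15.0,
) -> PipelineResult:
    """Run the full insertion pipeline on in-memory read pairs."""
    amplicon = design.amplicon_seq(genome)
    counts = StageCounts(input_pairs=len(raw_pairs))
    by_sample, dlog = demultiplex_and_filter_hops(raw_pairs, design)
    counts.demux_kept = sum(len(v) for v in by_sample.values())
    counts.demux_discarded = dlog.count("demux")

    events: list[InsertionEvent] = []
    reasons: dict[str, int] = {}
    for sample_id in sorted(by_sample):
        pairs = by_sample[sample_id]
        pairs, dlog = filter_phix(pairs, decoy_seq, k=phix_k, log=dlog)
        for pair in pairs:
            merged = merge_pairs(pair, min_overlap=min_overlap, max_mismatch_frac=max_mismatch_frac)
            if merged.merged:
                counts.merged += 1
                intervals = locus_intervals_of_read(merged.seq, amplicon)
                if not quality_filter(merged.qual, intervals, q_locus, q_rest):
                    counts.quality_dropped += 1
                    dlog.add(pair.read_id, "quality", "low_mean_q")
                    continue
                event, reason = call_merged(merged, design, genome, sample_id)
            else:
                counts.unmerged += 1
                rc2 = revcomp(pair.seq2)
                iv1 = [iv for iv in locus_intervals_of_read(pair.seq1, amplicon) if iv[0] == 0]
                iv2r = [iv for iv in locus_intervals_of_read(rc2, amplicon) if iv[1] == len(rc2)]
                iv2 = [(len(pair.seq2) - e, len(pair.seq2) - s) for s, e in iv2r]
                if not (quality_filter(pair.qual1, iv1, q_locus, q_rest)
                        and quality_filter(pair.qual2, iv2, q_locus, q_rest)):
                    counts.quality_dropped += 1
                    dlog.add(pair.read_id, "quality", "low_mean_q")
                    continue
                event, reason = call_unmerged(pair, design, genome, sample_id)
            reasons[reason] = reasons.get(reason, 0) + 1
            if event is not None:
                counts.called_events += 1
                events.append(event)
            else:
                dlog.add(pair.read_id, "call", reason)

    # collapse identical read copies before dedup; support the representative
    collapsed: dict[tuple, InsertionEvent] = {}
    for ev in sorted(events, key=lambda e: e.event_id):
        key = (ev.sample_id, ev.read_seq, ev.left_junction, ev.right_junction)
        if key in collapsed:
            collapsed[key].copies += 1
        else:
            collapsed[key] = ev
    candidates = list(collapsed.values())
    for ev in candidates:
        segment_donors(ev, genome)
        annotate_sources(ev, genome, design)
    counts.candidate_events = len(candidates)

    clusters, contaminants = dedup_events(
        candidates, amplicon, batch_map=batch_map, thresholds=thresholds,
        locus_bp=design.junction_flank_locus, donor_bp=design.junction_flank_donor,
    )
    counts.unique_insertions = len(clusters)
    counts.contaminants = len(contaminants)
    return PipelineResult(
        clusters=clusters,
        contaminants=contaminants,
        candidate_events=candidates,
        call_reasons=reasons,
        discard_log=dlog,
        counts=counts,
    )


def summarize(
    clusters: list[InsertionCluster],
    n_colonies: dict[str, int],
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-sample summary: unique insertions by donor class and complexity.

    Columns include the donor-count histogram (1-4+ fragments per insertion)
    and, when a reference sample is named, per-class fold changes against it.
    """
    rows = []
    samples = sorted({c.sample_id for c in clusters} | set(n_colonies))
    for sample in samples:
        mine = [c for c in clusters if c.sample_id == sample]
        class_counts: dict[str, int] = {}
        donor_hist = {1: 0, 2: 0, 3: 0, 4: 0}
        for c in mine:
            rep = c.representative
            classes = {seg.source_class or "nuclear" for seg in rep.segments}
            cls = classes.pop() if len(classes) == 1 else "mixed"
            class_counts[cls] = class_counts.get(cls, 0) + 1
            donor_hist[min(rep.n_donors, 4)] = donor_hist.get(min(rep.n_donors, 4), 0) + 1
        row = {
            "sample": sample,
            "n_colonies": n_colonies.get(sample, 0),
            "unique_insertions": len(mine),
            "read_support": sum(c.read_support for c in mine),
        }
        for cls in ("mtDNA", "Ty", "nuclear", "rDNA", "plasmid_2micron", "mixed"):
            row[f"n_{cls}"] = class_counts.get(cls, 0)
        for k in (1, 2, 3, 4):
            row[f"donors_{k}{'plus' if k == 4 else ''}"] = donor_hist[k]
        rows.append(row)
    df = pd.DataFrame(rows)
    if reference is not None and reference in set(df["sample"]):
        by_cond = {s: [c for c in clusters if c.sample_id == s] for s in samples}
        folds = fold_change_report(by_cond, {s: max(1, n_colonies.get(s, 1)) for s in samples}, reference)
        all_folds = folds[folds.source_class == "all"].set_index("condition")["fold_vs_reference"]
        df["fold_all_vs_ref"] = [all_folds.get(s, float("nan")) for s in df["sample"]]
    elif reference is not None:
        log.warning("reference sample %r absent; fold columns omitted", reference)
    return df


# ---------------------------------------------------------------------------
# file-based run
# ---------------------------------------------------------------------------

def _read_fastq(path: str | Path) -> dict[str, tuple[str, str]]:
    opener = gzip.open if str(path).endswith(".gz") else open
    out: dict[str, tuple[str, str]] = {}
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            rid = header[1:].split()[0]
            if rid.endswith("/1") or rid.endswith("/2"):
                rid = rid[:-2]
            out[rid] = (seq, qual)
    return out


def load_design(d: dict) -> AmpliconDesign:
    d = dict(d)
    d["sample_indexes"] = {
        sid: (tuple(ill), tuple(hom)) for sid, (ill, hom) in d.get("sample_indexes", {}).items()
    }
    return AmpliconDesign(**d)


def design_to_dict(design: AmpliconDesign) -> dict:
    d = asdict(design)
    d["sample_indexes"] = {
        sid: [list(ill), list(hom)] for sid, (ill, hom) in design.sample_indexes.items()
    }
    return d


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> Path:
    """Run the pipeline from a config mapping or YAML path; returns the output dir.

    Emits per-stage discard logs, the unique-insertions table, junction
    profiles, per-subject frequency tracks, optional feature enrichment, and a
    run manifest (versions, seed, config hash).
    """
    if not isinstance(config, dict):
        config_path = Path(config)
        with open(config_path) as fh:
            config = yaml.safe_load(fh)
    out_dir = Path(output_dir or config.get("output_dir", "breakins_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    for key in ("genome_fasta", "reads_r1", "reads_r2", "index_tsv"):
        if key not in config or not Path(config[key]).exists():
            raise FileNotFoundError(f"config key {key!r} missing or path does not exist: {config.get(key)}")

    class_intervals = {
        cls: [tuple(iv) for iv in ivals]
        for cls, ivals in (config.get("class_intervals") or {}).items()
    }
    genome_all = load_reference([config["genome_fasta"]], config["class_map"], class_intervals)
    decoy_name = config.get("decoy_name")
    decoy_seq = ""
    sequences = dict(genome_all.sequences)
    class_map = dict(genome_all.source_class_map)
    if decoy_name and decoy_name in sequences:
        decoy_seq = sequences.pop(decoy_name)
        class_map.pop(decoy_name, None)
    genome = ReferenceGenome(sequences, class_map, class_intervals)
    design = load_design(config["design"])

    index_df = pd.read_csv(config["index_tsv"], sep="\t", dtype=str)
    r1 = _read_fastq(config["reads_r1"])
    r2 = _read_fastq(config["reads_r2"])
    raw_pairs = []
    for row in index_df.itertuples(index=False):
        if row.read_id in r1 and row.read_id in r2:
            s1, q1 = r1[row.read_id]
            s2, q2 = r2[row.read_id]
            raw_pairs.append(RawPair(row.read_id, s1, q1, s2, q2, (row.index_i5, row.index_i7)))

    th = DedupThresholds(**(config.get("dedup_thresholds") or {}))
    result = run_from_objects(
        raw_pairs, genome, design, decoy_seq,
        batch_map=config.get("batch_map"),
        thresholds=th,
        min_overlap=config.get("min_overlap", 10),
        max_mismatch_frac=config.get("max_mismatch_frac", 0.1),
        phix_k=config.get("phix_k", 31),
        q_locus=config.get("q_locus", 25.0),
        q_rest=config.get("q_rest", 15.0),
    )

    # --- tabular outputs -------------------------------------------------
    pd.DataFrame(result.discard_log.rows, columns=["read_id", "stage", "reason"]).to_csv(
        out_dir / "discard_log.tsv", sep="\t", index=False
    )
    ev_rows = []
    for c in result.clusters + result.contaminants:
        rep = c.representative
        ev_rows.append({
            "cluster_id": c.cluster_id,
            "sample": c.sample_id,
            "batch": c.batch_id,
            "unique": c.unique,
            "representative": rep.event_id,
            "left_junction": rep.left_junction,
            "right_junction": rep.right_junction,
            "insert_len": rep.insert_len,
            "length_lower_bound": rep.length_lower_bound,
            "n_donors": rep.n_donors,
            "donors": ";".join(
                f"{s.subject}:{s.start}-{s.end}:{s.strand}:{s.source_class or 'NA'}"
                for s in rep.segments
            ),
            "members": len(c.members),
            "read_support": c.read_support,
            "mergeable": rep.mergeable,
        })
    pd.DataFrame(ev_rows).to_csv(out_dir / "unique_insertions.tsv", sep="\t", index=False)

    jp_rows = []
    for c in result.clusters:
        rep = c.representative
        if rep.length_lower_bound or rep.unmapped:
            continue
        p = junction_profile(rep, design, genome)
        jp_rows.append({"cluster_id": c.cluster_id, **asdict(p)})
    pd.DataFrame(jp_rows).to_csv(out_dir / "junction_profiles.tsv", sep="\t", index=False)

    n_colonies = config.get("n_colonies") or {}
    total_colonies = sum(n_colonies.values()) or max(1, result.counts.input_pairs)
    reps = [c.representative for c in result.clusters]
    mito = next((n for n, cl in genome.source_class_map.items() if cl == "mtDNA"), None)
    if mito:
        track = nucleotide_frequency(reps, mito, len(genome.sequences[mito]), total_colonies)
        _write_track(track, out_dir / "frequency_mtDNA.tsv")
    if config.get("ty1_fasta"):
        ty1 = load_reference([config["ty1_fasta"]], {"Ty1": "Ty"})
        realigned = []
        for rep in reps:
            segs = ty1_realign(rep, ty1)
            clone = InsertionEvent(**{**rep.__dict__, "segments": segs})
            realigned.append(clone)
        track = nucleotide_frequency(realigned, "Ty1", len(ty1.sequences["Ty1"]), total_colonies)
        _write_track(track, out_dir / "frequency_Ty1.tsv")

    if config.get("features_bed"):
        features = load_features(config["features_bed"], genome)
        donors = [
            (s.subject, s.start, s.end)
            for rep in reps
            for s in rep.segments
            if (s.source_class or "nuclear") not in features.excluded_sources
        ]
        territory = eligible_territory(
            genome, features.excluded_sources,
            extra_excluded=[(design.locus_name, design.amplicon_start, design.amplicon_end)],
        )
        enr_rows = []
        for fname, ivals in features.features.items():
            if not donors:
                break
            res = permutation_test(
                donors, ivals, territory,
                n_shuffles=config.get("n_shuffles", 100_000),
                seed=config.get("seed", 0),
                proximity_bp=(config.get("proximity_bp") or {}).get(fname),
            )
            enr_rows.append({
                "feature": fname, "observed": res.observed,
                "null_mean": res.null_mean, "p_value": res.p_value,
            })
        pd.DataFrame(enr_rows).to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)

    summary = summarize(result.clusters, n_colonies, config.get("reference_sample"))
    summary.to_csv(out_dir / "summary.tsv", sep="\t", index=False)

    manifest = {
        "breakins_version": breakins.__version__,
        "seed": config.get("seed", 0),
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "counts": asdict(result.counts),
        "call_reasons": result.call_reasons,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out_dir


def _write_track(track, path: Path) -> None:
    """bedGraph-style TSV: subject, start, end, count, per-1e5 frequency, percent."""
    freq = track.frequency_per_1e5()
    pct = track.percentage()
    with open(path, "w") as fh:
        fh.write("subject\tstart\tend\tn_t\tfreq_per_1e5\tpercent\n")
        i = 0
        n = len(track.n_t)
        while i < n:
            j = i
            while j < n and track.n_t[j] == track.n_t[i]:
                j += 1
            if track.n_t[i] > 0:
                fh.write(
                    f"{track.subject}\t{i}\t{j}\t{int(track.n_t[i])}"
                    f"\t{freq[i]:.6g}\t{pct[i]:.6g}\n"
                )
            i = j
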
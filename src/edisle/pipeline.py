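"""End-to-end orchestration: simulate → quantify → test → classify.

Every stage writes plain-text outputs into the run directory and is recorded
in a reproducibility manifest (config snapshot, seeds, package version,
output checksums, timestamps).  All stages are pure functions of the config
seeds, so re-running a manifest reproduces byte-identical outputs.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierConfig, run_classifier
from .quantify import (
    AlignedReads,
    IsoformProfile,
    SiteCallingConfig,
    aggregate_replicates,
    align_reads,
    analysis_site_set,
    count_bases,
)
from .reference import ReferenceAmplicon, default_amplicon, write_reference
from .simulate import Cohort, CohortConfig, isoform_name, simulate_cohort
from .stats import (
    COMPARISONS,
    differential_table,
    filter_analysis_set,
    site_correlation_matrix,
)

__all__ = ["PipelineConfig", "RunManifest", "StageError", "run_all", "report",
           "quantify_cohort"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    calling: SiteCallingConfig = field(default_factory=SiteCallingConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    comparisons: list[str] = field(default_factory=lambda: list(COMPARISONS))
    write_fastq: bool = True
    bootstrap_resamples: int = 2000

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "calling": vars(self.calling).copy(),
            "classifier": vars(self.classifier).copy(),
            "comparisons": list(self.comparisons),
            "write_fastq": self.write_fastq,
            "bootstrap_resamples": self.bootstrap_resamples,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        kwargs: dict = {}
        if "cohort" in d:
            kwargs["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "calling" in d:
            kwargs["calling"] = SiteCallingConfig(**d["calling"])
        if "classifier" in d:
            kwargs["classifier"] = ClassifierConfig(**d["classifier"])
        for key in ("comparisons", "write_fastq", "bootstrap_resamples"):
            if key in d:
                kwargs[key] = d[key]
        unknown = set(d) - {"cohort", "calling", "classifier", "comparisons",
                            "write_fastq", "bootstrap_resamples"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunManifest:
    config: dict
    version: str
    seeds: dict
    stages: dict = field(default_factory=dict)  # stage -> {files: {name: sha256}, time}

    def record(self, stage: str, out_dir: Path, files: Sequence[str]) -> None:
        sums = {}
        for name in files:
            p = out_dir / name
            if p.exists():
                sums[name] = hashlib.sha256(p.read_bytes()).hexdigest()
        self.stages[stage] = {
            "files": sums,
            "completed_at": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        }

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "version": self.version,
             "seeds": self.seeds, "stages": self.stages}, indent=2))


# ---------------------------------------------------------------------------
# quantify stage: code-packed single pass over reads
# ---------------------------------------------------------------------------

# per candidate position each read is coded 0 = A, 1 = G, 2 = other (2 bits)


def _encode_candidate_codes(aligned: AlignedReads) -> tuple[np.ndarray, np.ndarray]:
    """Pack each read's bases at the candidate positions into one integer.

    Returns unique codes and their counts; allows isoform enumeration over
    any later-chosen site subset without revisiting the reads.
    """
    sub = aligned.matrix[:, aligned.reference.offsets]
    trit = np.full(sub.shape, 2, dtype=np.int64)
    trit[sub == ord("A")] = 0
    trit[sub == ord("G")] = 1
    weights = 4 ** np.arange(sub.shape[1], dtype=np.int64)
    codes = trit @ weights
    return np.unique(codes, return_counts=True)


def _profile_from_codes(
    codes: np.ndarray,
    counts: np.ndarray,
    all_labels: Sequence[str],
    site_set: Sequence[str],
    cfg: SiteCallingConfig,
) -> IsoformProfile:
    """Isoform profile over `site_set` from packed candidate codes.

    Equivalent to `enumerate_isoforms` with the same passing sites: reads
    with a non-A/G base at any passing site are discarded; other candidate
    positions are ignored.
    """
    idx = [list(all_labels).index(lab) for lab in site_set]
    props: dict[frozenset[str], float] = {}
    tally: dict[frozenset[str], int] = {}
    discarded = 0
    for code, n in zip(codes, counts):
        members = []
        bad = False
        for i, lab in zip(idx, site_set):
            digit = (code >> (2 * i)) & 3
            if digit == 2:
                bad = True
                break
            if digit == 1:
                members.append(lab)
        if bad:
            discarded += int(n)
        else:
            key = frozenset(members)
            tally[key] = tally.get(key, 0) + int(n)
    classified = sum(tally.values())
    if classified == 0:
        raise ValueError("all reads discarded at called sites")
    props = {k: 100.0 * v / classified for k, v in tally.items()}
    if frozenset() not in props:
        props[frozenset()] = 0.0
    below = {s for s, p in props.items() if p < cfg.isoform_threshold}
    return IsoformProfile(
        proportions=props,
        classified_reads=classified,
        discarded_reads=discarded,
        below_threshold=below,
    )


def quantify_cohort(
    cohort: Cohort, cfg: SiteCallingConfig | None = None
) -> dict[str, pd.DataFrame | list[str]]:
    """Quantify every subject of a simulated cohort in one pass per replicate.

    Returns a dict with:
      site_pct    — subject × site editing percentages (replicate-averaged
                    base-count G-percentages);
      site_set    — analysis site labels (control-mean > detection threshold);
      isoforms    — subject × pattern relative proportions (replicate-averaged,
                    patterns over the analysis site set);
      features    — site + pattern features merged with subject metadata;
      base_counts — pooled per-position nucleotide counts over all reads.
    """
    cfg = cfg or SiteCallingConfig()
    ref = cohort.reference
    labels = ref.labels
    offsets = ref.offsets

    per_subject_codes: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    site_pct_rows = []
    pooled = None
    for subj in cohort.subjects:
        rep_pcts = []
        code_list = []
        for rep in range(cohort.config.replicates):
            batch = cohort.replicate_reads(subj, rep)
            aligned = align_reads(batch, ref, max_mismatch=cfg.max_mismatch)
            table = count_bases(aligned)
            counts = table.counts
            pooled = counts.to_numpy() if pooled is None else pooled + counts.to_numpy()
            a = counts["A"].to_numpy()[offsets]
            g = counts["G"].to_numpy()[offsets]
            with np.errstate(invalid="ignore"):
                pct = np.where(a + g > 0, 100.0 * g / np.maximum(a + g, 1), np.nan)
            rep_pcts.append(pct)
            code_list.append(_encode_candidate_codes(aligned))
        per_subject_codes[subj.subject_id] = code_list
        site_pct_rows.append(
            {"subject_id": subj.subject_id, "group": subj.group,
             **dict(zip([f"site_{lab}" for lab in labels],
                        np.nanmean(rep_pcts, axis=0)))}
        )
    site_pct = pd.DataFrame(site_pct_rows).set_index("subject_id")

    ctrl = site_pct[site_pct["group"] == "Ctrl"]
    basis = ctrl if len(ctrl) else site_pct
    site_cols = [f"site_{lab}" for lab in labels]
    chosen_cols = analysis_site_set(basis[site_cols].rename(
        columns=dict(zip(site_cols, labels))), cfg)
    site_set = [lab for lab in labels if lab in chosen_cols]

    iso_rows = []
    for subj in cohort.subjects:
        profiles = [
            _profile_from_codes(codes, counts, labels, site_set, cfg)
            for codes, counts in per_subject_codes[subj.subject_id]
        ]
        agg = aggregate_replicates(profiles)
        iso_rows.append(
            {"subject_id": subj.subject_id,
             **{f"iso_{isoform_name(s)}": p for s, p in agg.proportions.items()}}
        )
    isoforms = pd.DataFrame(iso_rows).set_index("subject_id").fillna(0.0)

    meta = cohort.metadata().set_index("subject_id")
    features = meta[["group", "MADRS", "IDSC30"]].join(
        site_pct[[f"site_{lab}" for lab in site_set]]).join(isoforms)

    base_counts = pd.DataFrame(pooled, columns=["A", "C", "G", "T", "other"])
    return {
        "site_pct": site_pct,
        "site_set": site_set,
        "isoforms": isoforms,
        "features": features,
        "base_counts": base_counts,
    }


def _feature_columns(features: pd.DataFrame, cfg: SiteCallingConfig) -> list[str]:
    """Analysis features: site percentages plus patterns whose control-group
    mean proportion is at least the inclusion threshold (plus NonEdited)."""
    site_cols = [c for c in features.columns if c.startswith("site_")]
    iso_cols = [c for c in features.columns if c.startswith("iso_")]
    ctrl = features[features["group"] == "Ctrl"]
    basis = ctrl if len(ctrl) else features
    keep_iso = [
        c for c in iso_cols
        if c == "iso_NonEdited" or basis[c].mean() >= cfg.isoform_threshold
    ]
    return site_cols + keep_iso


def run_all(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute simulate → quantify → test → classify into `out_dir`.

    Any stage failure raises StageError naming the stage; outputs of earlier
    stages remain on disk.  The manifest is (re)written after every stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.cohort.validate()
    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        seeds={"cohort": config.cohort.seed, "classifier": config.classifier.seed},
    )
    manifest_path = out / "manifest.json"

    # -- simulate ----------------------------------------------------------
    try:
        cohort = simulate_cohort(config.cohort)
        write_reference(cohort.reference, out / "reference.fasta", out / "sites.tsv")
        cohort.write(out, fastq=config.write_fastq)
        files = ["metadata.tsv", "truth.tsv", "reference.fasta", "sites.tsv"]
        manifest.record("simulate", out, files)
        manifest.write(manifest_path)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("simulate", exc) from exc

    # -- quantify ----------------------------------------------------------
    try:
        q = quantify_cohort(cohort, config.calling)
        q["site_pct"].to_csv(out / "site_pct.tsv", sep="\t")
        q["isoforms"].to_csv(out / "isoforms.tsv", sep="\t")
        q["features"].to_csv(out / "features.tsv", sep="\t")
        bc = q["base_counts"].copy()
        bc.insert(0, "offset", np.arange(len(bc)))
        bc.to_csv(out / "base_counts.tsv", sep="\t", index=False)
        (out / "site_set.txt").write_text("\n".join(q["site_set"]) + "\n")
        manifest.record("quantify", out, ["site_pct.tsv", "isoforms.tsv",
                                          "features.tsv", "base_counts.tsv",
                                          "site_set.txt"])
        manifest.write(manifest_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError("quantify", exc) from exc

    # -- test --------------------------------------------------------------
    try:
        features = q["features"]
        analysis, excluded = filter_analysis_set(features.reset_index())
        feat_cols = _feature_columns(features, config.calling)
        diff = differential_table(analysis, feat_cols, comparisons=config.comparisons)
        diff.to_csv(out / "differential.tsv", sep="\t", index=False)
        site_cols = [c for c in feat_cols if c.startswith("site_")]
        corr = site_correlation_matrix(analysis, site_cols)
        corr.to_csv(out / "correlation.tsv", sep="\t", index=False)
        (out / "exclusions.json").write_text(json.dumps(excluded))
        manifest.record("test", out, ["differential.tsv", "correlation.tsv",
                                      "exclusions.json"])
        manifest.write(manifest_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError("test", exc) from exc

    # -- classify ----------------------------------------------------------
    try:
        rep = run_classifier(
            analysis, feat_cols, config.classifier,
            n_boot=config.bootstrap_resamples,
        )
        (out / "classifier_report.json").write_text(json.dumps(rep.to_dict(), indent=2))
        rep.roc.to_csv(out / "roc.tsv", sep="\t", index=False)
        manifest.record("classify", out, ["classifier_report.json", "roc.tsv"])
        manifest.write(manifest_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", exc) from exc

    return manifest


def report(out_dir: str | Path) -> str:
    """Human-readable one-page summary of a (possibly partial) run."""
    out = Path(out_dir)
    lines = ["editing-island pipeline report", "=" * 32]
    stages_done = []
    if (out / "site_set.txt").exists():
        stages_done.append("quantify")
        sites = (out / "site_set.txt").read_text().split()
        lines.append(f"called sites ({len(sites)}): {', '.join(sites)}")
    if (out / "isoforms.tsv").exists():
        iso = pd.read_csv(out / "isoforms.tsv", sep="\t", index_col=0)
        top = iso.mean().sort_values(ascending=False).head(6)
        lines.append("top patterns (cohort mean relative proportion, %):")
        for name, val in top.items():
            lines.append(f"  {name.removeprefix('iso_'):>12s}  {val:8.3f}")
    if (out / "differential.tsv").exists():
        stages_done.append("test")
        diff = pd.read_csv(out / "differential.tsv", sep="\t")
        lines.append("significant features per comparison (BH-adjusted p < 0.05):")
        for comp, block in diff.groupby("comparison"):
            sig = block.loc[block["significant"], "feature"].tolist()
            lines.append(f"  {comp}: {', '.join(sig) if sig else '(none)'}")
    if (out / "classifier_report.json").exists():
        stages_done.append("classify")
        rep = json.loads((out / "classifier_report.json").read_text())
        lo, hi = rep["auc_ci"]
        lines.append(
            f"classifier (held-out): AUC = {rep['auc']:.3f} "
            f"[{lo:.3f}; {hi:.3f}], sensitivity = {rep['sensitivity']:.2f}, "
            f"specificity = {rep['specificity']:.2f}"
        )
    if not stages_done:
        lines.append("no stages completed")
    else:
        missing = [s for s in ("quantify", "test", "classify") if s not in stages_done]
        if missing:
            lines.append(f"missing stages: {', '.join(missing)}")
    return "\n".join(lines) + "\n"
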
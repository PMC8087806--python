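"""Synthetic targeted-amplicon cohort generator.

Emulates deep amplicon sequencing of a short editing island in whole blood:

* each transcript molecule carries a *co-editing pattern* — the set of sites
  edited on that same molecule (the empty set is the non-edited molecule);
* a sample is a multinomial draw of reads over those patterns, with an
  independent per-base substitution error;
* subjects vary around their group's mean pattern frequencies (Dirichlet
  subject effects, which also induce the positive inter-site correlation seen
  across subjects);
* patient groups carry a configurable down-scaling of all edited patterns,
  with the lost mass moving to the non-edited pattern (the mirror effect);
* each subject is sequenced as independent technical replicates (default 5);
* clinical severity scores on two correlated rating scales (MADRS and
  IDS-C30) are drawn per group with a configurable squared correlation
  (default 0.90) and are near zero for controls.

A truth table records the generating pattern frequencies per subject so that
recovery by the quantification pipeline can be tested.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .reference import ReferenceAmplicon, default_amplicon

GROUPS = ("Ctrl", "DEP", "SA")

SiteSet = frozenset


def isoform_name(sites: frozenset[str]) -> str:
    """Human name of a co-editing pattern: 'NonEdited' or e.g. 'B,C'."""
    return "NonEdited" if not sites else ",".join(sorted(sites))


def parse_isoform_name(name: str) -> frozenset[str]:
    if name in ("NonEdited", "", "-"):
        return frozenset()
    return frozenset(name.split(","))


@dataclass(frozen=True)
class IsoformDistribution:
    """Frequencies of co-editing patterns (fractions summing to 1).

    Keys are frozensets of site labels; the empty set is the non-edited
    molecule.  Under the shipped defaults every multi-site pattern contains
    the dominant site B, matching the observation that multi-site molecules
    without the dominant site are not seen.
    """

    probs: Mapping[frozenset[str], float]

    def __post_init__(self) -> None:
        probs = {frozenset(k): float(v) for k, v in self.probs.items()}
        object.__setattr__(self, "probs", probs)
        if any(v < 0 for v in probs.values()):
            raise ValueError("pattern probabilities must be non-negative")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern probabilities sum to {total}, not 1")

    def validate_against(self, ref: ReferenceAmplicon) -> None:
        known = set(ref.labels)
        for s in self.probs:
            if not set(s) <= known:
                raise ValueError(f"pattern {isoform_name(s)} references unknown site(s)")

    def site_level(self, label: str) -> float:
        """True per-site editing fraction = sum over patterns containing the site."""
        return sum(p for s, p in self.probs.items() if label in s)

    def site_levels(self, labels: Iterable[str]) -> dict[str, float]:
        return {lab: self.site_level(lab) for lab in labels}

    def ordered(self) -> tuple[list[frozenset[str]], np.ndarray]:
        """Stable ordering (by name) of patterns and their probability vector."""
        keys = sorted(self.probs, key=isoform_name)
        return keys, np.array([self.probs[k] for k in keys], dtype=float)

    def scale_edited(self, factor: float) -> "IsoformDistribution":
        """Multiply every edited pattern by `factor`; the non-edited pattern
        absorbs the freed mass (the group-effect model)."""
        if factor < 0:
            raise ValueError("factor must be >= 0")
        out = {s: p * factor for s, p in self.probs.items() if s}
        out[frozenset()] = 1.0 - sum(out.values())
        return IsoformDistribution(out)


def default_control_distribution() -> IsoformDistribution:
    """Shipped control-group pattern table.

    Site levels implied: B = 20 %, C = 0.6 %, E = 0.45 %, F = 0.3 %,
    D = 0.25 %; all other candidate positions unedited in truth (background
    there arises only through the sequencing error rate).
    """
    return IsoformDistribution(
        {
            frozenset(): 0.80,
            frozenset("B"): 0.184,
            frozenset(["B", "C"]): 0.006,
            frozenset(["B", "E"]): 0.0045,
            frozenset(["B", "F"]): 0.003,
            frozenset(["B", "D"]): 0.0025,
        }
    )


@dataclass(frozen=True)
class GroupSeverity:
    """Per-group severity-score model (means/SDs of the two rating scales)."""

    madrs_mean: float
    madrs_sd: float
    idsc_mean: float
    idsc_sd: float


#: Defaults follow the study cohort's clinical characteristics.
DEFAULT_SEVERITY: dict[str, GroupSeverity] = {
    "Ctrl": GroupSeverity(0.65, 1.25, 2.01, 2.46),
    "DEP": GroupSeverity(28.99, 9.55, 34.87, 10.02),
    "SA": GroupSeverity(23.94, 10.99, 32.73, 12.18),
}


@dataclass
class CohortConfig:
    """Everything needed to generate a cohort; defaults are the study conditions."""

    n_ctrl: int = 99
    n_dep: int = 101
    n_sa: int = 84
    control_distribution: IsoformDistribution = field(
        default_factory=default_control_distribution
    )
    #: multiplicative effect on edited-pattern mass, per patient group
    group_effects: dict[str, float] = field(
        default_factory=lambda: {"DEP": 0.7, "SA": 0.6}
    )
    #: explicit per-group pattern tables; override the multiplicative effects
    group_distributions: dict[str, IsoformDistribution] | None = None
    #: log-normal sigma of the shared per-subject editing propensity factor
    #: (multiplies all edited-pattern mass; drives the island-wide positive
    #: inter-site correlation across subjects)
    propensity_sigma: float = 0.12
    #: Dirichlet concentration for residual per-pattern subject variability
    concentration: float = 30_000.0
    reads_per_replicate: int = 10_000
    replicates: int = 5
    error_rate: float = 4e-4
    severity: dict[str, GroupSeverity] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY)
    )
    #: target squared correlation between the two severity scales
    severity_r2: float = 0.90
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_ctrl, self.n_dep, self.n_sa) < 0:
            raise ValueError("group sizes must be >= 0")
        if self.n_ctrl + self.n_dep + self.n_sa == 0:
            raise ValueError("cohort must contain at least one subject")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if self.propensity_sigma < 0:
            raise ValueError("propensity_sigma must be >= 0")
        if not 0 <= self.severity_r2 <= 1:
            raise ValueError("severity_r2 must be in [0, 1]")

    def group_distribution(self, group: str) -> IsoformDistribution:
        if self.group_distributions and group in self.group_distributions:
            return self.group_distributions[group]
        if group == "Ctrl":
            return self.control_distribution
        return self.control_distribution.scale_edited(self.group_effects[group])

    def group_sizes(self) -> dict[str, int]:
        return {"Ctrl": self.n_ctrl, "DEP": self.n_dep, "SA": self.n_sa}

    # -- YAML round trip -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_ctrl": self.n_ctrl,
            "n_dep": self.n_dep,
            "n_sa": self.n_sa,
            "control_distribution": {
                isoform_name(k): v for k, v in self.control_distribution.probs.items()
            },
            "group_effects": dict(self.group_effects),
            **(
                {
                    "group_distributions": {
                        g: {isoform_name(k): v for k, v in d.probs.items()}
                        for g, d in self.group_distributions.items()
                    }
                }
                if self.group_distributions
                else {}
            ),
            "propensity_sigma": self.propensity_sigma,
            "concentration": self.concentration,
            "reads_per_replicate": self.reads_per_replicate,
            "replicates": self.replicates,
            "error_rate": self.error_rate,
            "severity": {
                g: [s.madrs_mean, s.madrs_sd, s.idsc_mean, s.idsc_sd]
                for g, s in self.severity.items()
            },
            "severity_r2": self.severity_r2,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        kwargs = dict(d)
        if "control_distribution" in kwargs:
            kwargs["control_distribution"] = IsoformDistribution(
                {parse_isoform_name(k): v for k, v in kwargs["control_distribution"].items()}
            )
        if kwargs.get("group_distributions"):
            kwargs["group_distributions"] = {
                g: IsoformDistribution(
                    {parse_isoform_name(k): v for k, v in table.items()}
                )
                for g, table in kwargs["group_distributions"].items()
            }
        if "severity" in kwargs:
            kwargs["severity"] = {
                g: GroupSeverity(*vals) for g, vals in kwargs["severity"].items()
            }
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

_QUAL_CHAR = chr(37 + 33)  # constant Q37, Phred+33

# for each original base code, the three substitution alternatives
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ALTS = {b: np.array([x for x in _BASES if x != b], dtype=np.uint8) for b in _BASES}


@dataclass
class ReadBatch:
    """A set of full-length amplicon reads held as an ASCII uint8 matrix."""

    ids: list[str]
    matrix: np.ndarray  # shape (n_reads, amplicon_length), uint8 ASCII

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def sequences(self) -> list[str]:
        return [row.tobytes().decode("ascii") for row in self.matrix]

    def to_fastq(self, path: str | Path) -> None:
        """Write 4-line FASTQ records (Phred+33, constant Q37); .gz transparent."""
        path = Path(path)
        qual = _QUAL_CHAR * self.matrix.shape[1]
        buf = io.StringIO()
        for rid, row in zip(self.ids, self.matrix):
            buf.write(f"@{rid}\n{row.tobytes().decode('ascii')}\n+\n{qual}\n")
        data = buf.getvalue().encode("ascii")
        if path.suffix == ".gz":
            # mtime and name fixed so identical reads give byte-identical files
            with open(path, "wb") as raw:
                with gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0) as fh:
                    fh.write(data)
        else:
            path.write_bytes(data)


def simulate_reads(
    dist: IsoformDistribution,
    ref: ReferenceAmplicon,
    depth: int,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    read_prefix: str = "read",
) -> ReadBatch:
    """Draw `depth` full-length amplicon reads from a pattern distribution.

    A read drawn with pattern S carries 'G' at the offsets of the sites in S
    and the reference base elsewhere; an independent substitution error is
    then applied per base at `error_rate` (uniform over the three alternative
    bases).  Deterministic given the seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    dist.validate_against(ref)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    keys, probs = dist.ordered()
    counts = rng.multinomial(depth, probs)
    length = len(ref)
    matrix = np.tile(ref.encoded(), (depth, 1))
    g_code = ord("G")
    row = 0
    for sites, n in zip(keys, counts):
        if n and sites:
            offs = [ref.offset_of(lab) for lab in sites]
            matrix[row : row + n, offs] = g_code
        row += n
    # shuffle so read order does not encode the pattern
    rng.shuffle(matrix, axis=0)

    if error_rate > 0:
        n_err = rng.binomial(depth * length, error_rate)
        if n_err:
            flat = rng.choice(depth * length, size=n_err, replace=False)
            rows, cols = np.divmod(flat, length)
            picks = rng.integers(0, 3, size=n_err)
            orig = matrix[rows, cols]
            new = np.empty(n_err, dtype=np.uint8)
            for b, alts in _ALTS.items():
                mask = orig == b
                new[mask] = alts[picks[mask]]
            matrix[rows, cols] = new

    ids = [f"{read_prefix}_{i}" for i in range(depth)]
    return ReadBatch(ids=ids, matrix=matrix)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class SubjectTruth:
    subject_id: str
    group: str
    madrs: int
    idsc30: int
    distribution: IsoformDistribution  # subject-level truth (shared by replicates)
    replicate_seeds: list[int]


@dataclass
class Cohort:
    """A simulated cohort: truth plus deterministic on-demand read generation.

    Reads are regenerated from recorded per-replicate seeds rather than held
    in memory, so the same cohort object always yields byte-identical FASTQ.
    """

    config: CohortConfig
    reference: ReferenceAmplicon
    subjects: list[SubjectTruth]

    def replicate_reads(self, subject: SubjectTruth, rep: int) -> ReadBatch:
        return simulate_reads(
            subject.distribution,
            self.reference,
            depth=self.config.reads_per_replicate,
            error_rate=self.config.error_rate,
            seed=np.random.default_rng(subject.replicate_seeds[rep]),
            read_prefix=f"{subject.subject_id}_r{rep + 1}",
        )

    def iter_replicates(self):
        """Yield (subject, replicate_index, ReadBatch) over the whole cohort."""
        for subj in self.subjects:
            for rep in range(self.config.replicates):
                yield subj, rep, self.replicate_reads(subj, rep)

    def metadata(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            files = ";".join(
                f"{s.subject_id}_{r + 1}.fastq.gz" for r in range(self.config.replicates)
            )
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "MADRS": s.madrs,
                    "IDSC30": s.idsc30,
                    "replicate_files": files,
                }
            )
        return pd.DataFrame(rows)

    def truth_table(self) -> pd.DataFrame:
        """Per subject × replicate: true pattern frequencies and site levels."""
        labels = self.reference.labels
        rows = []
        for s in self.subjects:
            site_truth = s.distribution.site_levels(labels)
            for rep in range(self.config.replicates):
                row: dict = {
                    "subject_id": s.subject_id,
                    "replicate": rep + 1,
                    "group": s.group,
                    "MADRS": s.madrs,
                    "IDSC30": s.idsc30,
                }
                for k, v in sorted(s.distribution.probs.items(), key=lambda kv: isoform_name(kv[0])):
                    row[f"iso_{isoform_name(k)}"] = v
                for lab in labels:
                    row[f"site_{lab}"] = site_truth[lab]
                rows.append(row)
        return pd.DataFrame(rows).fillna(0.0)

    def write(self, out_dir: str | Path, fastq: bool = True) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metadata().to_csv(out / "metadata.tsv", sep="\t", index=False)
        self.truth_table().to_csv(out / "truth.tsv", sep="\t", index=False)
        if fastq:
            fq = out / "fastq"
            fq.mkdir(exist_ok=True)
            for subj, rep, batch in self.iter_replicates():
                batch.to_fastq(fq / f"{subj.subject_id}_{rep + 1}.fastq.gz")


def _draw_severity(
    rng: np.random.Generator, model: GroupSeverity, n: int, r2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate-normal severity scores, rounded to integers and clipped at 0."""
    r = float(np.sqrt(r2))
    cov = [
        [model.madrs_sd**2, r * model.madrs_sd * model.idsc_sd],
        [r * model.madrs_sd * model.idsc_sd, model.idsc_sd**2],
    ]
    scores = rng.multivariate_normal([model.madrs_mean, model.idsc_mean], cov, size=n)
    scores = np.clip(np.rint(scores), 0, None).astype(int)
    return scores[:, 0], scores[:, 1]


def simulate_cohort(
    config: CohortConfig, ref: ReferenceAmplicon | None = None
) -> Cohort:
    """Generate a cohort of subjects with truth and reproducible reads.

    Subject-level pattern frequencies combine two effects:

    * a shared editing-propensity factor per subject (log-normal, mean 1,
      sigma = config.propensity_sigma) that multiplies the mass of every
      edited pattern — editing across an island is co-regulated by the same
      enzymatic activity, which is what makes all per-site levels positively
      correlated across subjects;
    * a Dirichlet draw around the propensity-scaled group mean
      (concentration = config.concentration) adding residual per-pattern
      variability while keeping the vector a valid frequency distribution.
    """
    config.validate()
    ref = ref or default_amplicon()
    config.control_distribution.validate_against(ref)
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root)

    subjects: list[SubjectTruth] = []
    idx = 1
    for group in GROUPS:
        n = config.group_sizes()[group]
        if n == 0:
            continue
        gdist = config.group_distribution(group)
        keys, mean = gdist.ordered()
        madrs, idsc = _draw_severity(rng, config.severity[group], n, config.severity_r2)
        edited_mass = 1.0 - gdist.probs.get(frozenset(), 0.0)
        for i in range(n):
            sig = config.propensity_sigma
            factor = float(rng.lognormal(-0.5 * sig**2, sig)) if sig > 0 else 1.0
            if edited_mass > 0:
                factor = min(factor, 0.99 / edited_mass)  # keep a valid table
            _, subj_mean = gdist.scale_edited(factor).ordered()
            alphas = np.clip(config.concentration * subj_mean, 1e-9, None)
            p = rng.dirichlet(alphas)
            sdist = IsoformDistribution({k: float(v) for k, v in zip(keys, p / p.sum())})
            rep_seeds = [
                int(rng.integers(0, 2**31 - 1)) for _ in range(config.replicates)
            ]
            subjects.append(
                SubjectTruth(
                    subject_id=f"S{idx:04d}",
                    group=group,
                    madrs=int(madrs[i]),
                    idsc30=int(idsc[i]),
                    distribution=sdist,
                    replicate_seeds=rep_seeds,
                )
            )
            idx += 1
    return Cohort(config=config, reference=ref, subjects=subjects)
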
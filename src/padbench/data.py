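"""Labelled dataset assembly for the hierarchical enzyme-classification tasks.

Inputs are a FASTA of amino acid sequences and a TSV annotation table
(``id<TAB>ec1;ec2;...``, empty EC field = non-enzyme).  From these the
module builds the two-level labelling — task 1: enzyme vs non-enzyme;
task 2: the enzyme class, i.e. the first EC digit (1 oxidoreductases,
2 transferases, 3 hydrolases, 4 lyases, 5 isomerases, 6 ligases,
7 translocases) — applies the length filter, expands entries annotated
with several enzyme classes into one sample per distinct class, and
draws repeated random train/validation/test partitions.

Expanded duplicates share an ``origin_id`` and are always assigned to the
same partition, so a protein can never appear in both train and test.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .codec import read_fasta

logger = logging.getLogger(__name__)

PARTS = ("train", "val", "test")
ENZYME_CLASSES = tuple(range(1, 8))


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotatedSequence:
    id: str
    residues: str
    ec_numbers: tuple[str, ...] = ()

    @property
    def first_digits(self) -> tuple[int, ...]:
        """Distinct enzyme classes (EC first digits), sorted."""
        return tuple(sorted({int(ec.split(".")[0]) for ec in self.ec_numbers}))


@dataclass(frozen=True)
class LabeledSample:
    id: str
    residues: str
    task1_label: int                  # 0 non-enzyme, 1 enzyme
    task2_label: int | None = None    # enzyme class 1..7, present iff enzyme
    origin_id: str = ""

    def __post_init__(self):
        if (self.task2_label is not None) != (self.task1_label == 1):
            raise DatasetError("task2 label present iff the sample is an enzyme")


@dataclass
class SplitPlan:
    """Repeated random partition assignments, grouped by origin."""

    n_repeats: int
    fractions: tuple[float, float, float]
    seed: int
    assignments: list[dict[str, str]]   # per repeat: sample id -> part


def validate_ec(ec: str) -> str:
    parts = ec.split(".")
    if len(parts) != 4:
        raise DatasetError(f"malformed EC number {ec!r}: need 4 dot-separated fields")
    if not parts[0].isdigit() or not 1 <= int(parts[0]) <= 7:
        raise DatasetError(f"malformed EC number {ec!r}: first field must be 1-7")
    return ec


def read_annotation_tsv(path) -> dict[str, tuple[str, ...]]:
    """Read ``id<TAB>ec1;ec2;...`` rows; an empty EC field means non-enzyme."""
    table: dict[str, tuple[str, ...]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            rid = row[0].strip()
            if rid in table:
                raise DatasetError(f"duplicate id {rid!r} in annotation table")
            raw = row[1].strip() if len(row) > 1 else ""
            ecs = tuple(validate_ec(e.strip()) for e in raw.split(";") if e.strip())
            table[rid] = ecs
    return table


def load_annotations(fasta_path, tsv_path) -> list[AnnotatedSequence]:
    """Join FASTA sequences with the EC annotation table.

    Sequences absent from the table get an empty EC list (non-enzymes);
    a table id missing from the FASTA is an error.
    """
    seqs = read_fasta(fasta_path)
    ids = [rid for rid, _ in seqs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DatasetError(f"duplicate FASTA ids: {dupes}")
    table = read_annotation_tsv(tsv_path)
    missing = sorted(set(table) - set(ids))
    if missing:
        raise DatasetError(f"annotation ids missing from FASTA: {missing}")
    return [AnnotatedSequence(rid, seq, table.get(rid, ())) for rid, seq in seqs]


def filter_by_length(records, max_len: int = 1000):
    """Keep records with length <= ``max_len`` (boundary inclusive)."""
    kept = [r for r in records if len(r.residues) <= max_len]
    discarded = len(records) - len(kept)
    if discarded:
        logger.info("length filter (<= %d): discarded %d of %d records",
                    max_len, discarded, len(records))
    return kept


def expand_multi_ec(records) -> list[LabeledSample]:
    """One sample per distinct enzyme class of each record.

    A record with ``k >= 2`` distinct EC first digits yields ``k`` samples
    sharing its id as ``origin_id``; duplicate first digits collapse.
    Records without EC annotation become single non-enzyme samples.
    """
    samples: list[LabeledSample] = []
    for rec in records:
        digits = rec.first_digits
        if not digits:
            samples.append(LabeledSample(rec.id, rec.residues, 0, None, rec.id))
        elif len(digits) == 1:
            samples.append(LabeledSample(rec.id, rec.residues, 1, digits[0], rec.id))
        else:
            for d in digits:
                samples.append(
                    LabeledSample(f"{rec.id}|EC{d}", rec.residues, 1, d, rec.id))
    return samples


def task_label(sample: LabeledSample, task: int) -> int:
    if task == 1:
        return sample.task1_label
    if task == 2:
        if sample.task2_label is None:
            raise DatasetError(f"sample {sample.id} is not an enzyme; no task-2 label")
        return sample.task2_label
    raise DatasetError(f"task must be 1 or 2, got {task}")


def make_splits(samples, fractions=(0.70, 0.15, 0.15), n_repeats: int = 10,
                seed: int = 0, stratify: bool = False) -> SplitPlan:
    """Draw ``n_repeats`` random train/val/test partitions.

    Groups sharing an ``origin_id`` are assigned as a unit (greedy
    largest-deficit placement after a seeded shuffle), so expanded
    duplicates never straddle partitions.  With ``stratify=True`` the
    shuffle-and-place happens within (task1, task2) strata.
    """
    if len(fractions) != 3 or abs(sum(fractions) - 1) > 1e-9:
        raise DatasetError(f"fractions must be 3 values summing to 1, got {fractions}")
    samples = list(samples)
    if len(samples) < 3:
        raise DatasetError("need at least 3 samples to split")

    groups: dict[str, list[LabeledSample]] = defaultdict(list)
    for s in samples:
        groups[s.origin_id or s.id].append(s)
    group_ids = sorted(groups)
    n_total = len(samples)

    rng = np.random.default_rng(seed)
    assignments: list[dict[str, str]] = []
    for _ in range(n_repeats):
        order = list(rng.permutation(len(group_ids)))
        if stratify:
            key = {}
            for gi in group_ids:
                s0 = groups[gi][0]
                key[gi] = (s0.task1_label, s0.task2_label or 0)
            order.sort(key=lambda k: key[group_ids[k]])
        targets = [f * n_total for f in fractions]
        counts = [0.0, 0.0, 0.0]
        assign: dict[str, str] = {}
        for k in order:
            gid = group_ids[k]
            deficits = [targets[p] - counts[p] for p in range(3)]
            part = int(np.argmax(deficits))
            for s in groups[gid]:
                assign[s.id] = PARTS[part]
            counts[part] += len(groups[gid])
        assignments.append(assign)
    return SplitPlan(n_repeats, tuple(fractions), seed, assignments)


def save_split_plan(plan: SplitPlan, path) -> None:
    """Serialize as CSV ``repeat,id,part``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["repeat", "id", "part"])
        for rep, assign in enumerate(plan.assignments):
            for sid in sorted(assign):
                w.writerow([rep, sid, assign[sid]])


def load_split_plan(path, fractions=(0.70, 0.15, 0.15), seed: int = 0) -> SplitPlan:
    by_rep: dict[int, dict[str, str]] = defaultdict(dict)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for rep, sid, part in reader:
            by_rep[int(rep)][sid] = part
    reps = [by_rep[r] for r in sorted(by_rep)]
    return SplitPlan(len(reps), tuple(fractions), seed, reps)
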
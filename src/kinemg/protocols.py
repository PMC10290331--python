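"""Training/evaluation experiment designs.

All runners share one convention: repetitions of every retained task are
split per subject into train/validation/test (15/1/2 at the full 18
repetitions, scaled proportionally for smaller sessions); held-out tasks
appear only in the new-motion test sets, held-out subjects only in the
new-subject sets.  Min-max normalization is fitted per subject on that
subject's *training* repetitions only, so no statistic of the test data
leaks into training.

Conditions:

* general           — trained on every subject except the held-out one.
* fine-tuned        — the general model, weight-transferred and briefly
                      re-trained on the held-out subject (lr 1e-4,
                      max 20 epochs by default).
* subject-specific  — freshly initialized, trained on one subject only.
* added-general     — trained on *all* subjects at once.

Every stage derives its RNG stream from one master seed, so each stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone

from .metrics import MetricReport, report
from .models import BaseEmgRegressor, transfer_weights
from .preprocess import ChannelScaler, SequencePair, build_features, segment_sequences, savgol_positions
from .synth import RawRecording

__all__ = [
    "SplitPlan",
    "ProtocolData",
    "ProtocolResult",
    "make_split_plan",
    "prepare_protocol_data",
    "pairs_from_recordings",
    "run_general",
    "run_finetune",
    "run_subject_specific",
    "run_loo",
    "run_repetition_sweep",
    "run_input_ablation",
    "run_added_general",
]

_STAGE = {"split": 0, "general": 1, "finetune": 2, "subject_specific": 3,
          "added_general": 4, "sweep": 5, "ablation": 6, "loo": 7}


def _substream(seed: int, stage: str, extra: int = 0) -> int:
    """A named, reproducible child seed below 2**31."""
    ss = np.random.SeedSequence([int(seed), _STAGE[stage], int(extra)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class SplitPlan:
    """Disjoint train/val/test assignment of (subject, task, repetition)."""

    train: set = field(default_factory=set)
    val: set = field(default_factory=set)
    test: set = field(default_factory=set)
    heldout_subjects: tuple = ()
    heldout_tasks: tuple = ()
    seed: int = 0

    def assert_no_leakage(self):
        if (self.train & self.val) or (self.train & self.test) or (self.val & self.test):
            raise AssertionError("split plan partitions overlap")
        for key in self.train | self.val | self.test:
            if key[1] in self.heldout_tasks:
                raise AssertionError("held-out task leaked into a split")


def _default_counts(n_reps: int) -> tuple[int, int]:
    """(n_val, n_test) scaled from the 15/1/2 split at 18 repetitions."""
    n_val = max(1, round(n_reps * 1 / 18))
    n_test = max(1, round(n_reps * 2 / 18))
    if n_val + n_test >= n_reps:
        raise ValueError(f"{n_reps} repetitions are too few to split")
    return n_val, n_test


def make_split_plan(keys, heldout_subjects=(), heldout_tasks=(),
                    n_val: int | None = None, n_test: int | None = None,
                    seed: int = 0) -> SplitPlan:
    """Assign repetitions of every (subject, task) to train/val/test.

    ``keys`` is an iterable of (subject, task, repetition) labels.  Held-out
    subjects still get a split (their training part feeds fine-tuning);
    held-out tasks are excluded from every partition and reserved for the
    new-motion evaluation.
    """
    keys = sorted(set(keys))
    rng = np.random.default_rng(_substream(seed, "split"))
    by_st: dict[tuple[int, int], list[int]] = {}
    for s, t, r in keys:
        by_st.setdefault((s, t), []).append(r)
    plan = SplitPlan(heldout_subjects=tuple(heldout_subjects),
                     heldout_tasks=tuple(heldout_tasks), seed=seed)
    for (s, t), reps in sorted(by_st.items()):
        if t in plan.heldout_tasks:
            continue
        reps = sorted(reps)
        nv, nt = (n_val, n_test)
        if nv is None or nt is None:
            dv, dt = _default_counts(len(reps))
            nv, nt = (dv if nv is None else nv, dt if nt is None else nt)
        order = rng.permutation(len(reps))
        test_r = {reps[i] for i in order[:nt]}
        val_r = {reps[i] for i in order[nt:nt + nv]}
        for r in reps:
            bucket = plan.test if r in test_r else plan.val if r in val_r else plan.train
            bucket.add((s, t, r))
    plan.assert_no_leakage()
    return plan


@dataclass
class ProtocolData:
    """Per-subject-normalized sequence pairs plus their split plan."""

    pairs: list[SequencePair]
    plan: SplitPlan
    scalers: dict[int, dict[str, ChannelScaler]]

    @property
    def subjects(self) -> list[int]:
        return sorted({p.subject for p in self.pairs})

    def select(self, *, subjects=None, not_subjects=(), tasks=None,
               not_tasks=(), split=None) -> list[SequencePair]:
        bucket = None if split is None else getattr(self.plan, split)
        out = []
        for p in self.pairs:
            if subjects is not None and p.subject not in subjects:
                continue
            if p.subject in not_subjects or p.task in not_tasks:
                continue
            if tasks is not None and p.task not in tasks:
                continue
            if bucket is not None and p.key not in bucket:
                continue
            out.append(p)
        return out


def pairs_from_recordings(recordings: list[RawRecording], feature_config: str = "ALL",
                          savgol_window: int = 31) -> list[SequencePair]:
    """Preprocess recordings up to (but excluding) normalization."""
    from .preprocess import baseline_correct, moving_rms, repair_outliers
    pairs = []
    for rec in recordings:
        emg = baseline_correct(rec.emg, rec.emg_rate)
        emg, _ = repair_outliers(emg, rec.emg_rate)
        t60 = np.arange(rec.motion.shape[0]) / rec.motion_rate
        envelope = moving_rms(emg, rec.emg_rate, t60)
        motion = rec.motion.copy()
        motion[:, :6] = savgol_positions(motion[:, :6], window_frames=savgol_window)
        features = build_features(motion, feature_config, rate=rec.motion_rate)
        pairs.extend(segment_sequences(features, envelope, rec.cue_onsets,
                                       rec.labels, rec.subject_id,
                                       feature_config=feature_config))
    return pairs


def prepare_protocol_data(pairs: list[SequencePair], heldout_subjects=(),
                          heldout_tasks=(), n_val=None, n_test=None,
                          seed: int = 0) -> ProtocolData:
    """Split and normalize un-normalized pairs for an experiment.

    Normalization parameters are fitted per subject on the concatenation of
    that subject's training repetitions and then applied (with clipping) to
    all of the subject's sequences.
    """
    plan = make_split_plan([p.key for p in pairs], heldout_subjects,
                           heldout_tasks, n_val, n_test, seed)
    scalers: dict[int, dict[str, ChannelScaler]] = {}
    normalized: list[SequencePair] = []
    subjects = sorted({p.subject for p in pairs})
    for s in subjects:
        train_pairs = [p for p in pairs if p.subject == s and p.key in plan.train]
        if not train_pairs:
            raise ValueError(f"subject {s} has no training repetitions to fit normalization on")
        m_sc = ChannelScaler("motion").fit(np.vstack([p.motion for p in train_pairs]))
        e_sc = ChannelScaler("emg").fit(np.vstack([p.emg for p in train_pairs]))
        scalers[s] = {"motion": m_sc, "emg": e_sc}
        for p in pairs:
            if p.subject != s:
                continue
            normalized.append(SequencePair(
                motion=m_sc.transform(p.motion), emg=e_sc.transform(p.emg),
                subject=p.subject, task=p.task, repetition=p.repetition,
                feature_config=p.feature_config))
    return ProtocolData(pairs=normalized, plan=plan, scalers=scalers)


@dataclass
class ProtocolResult:
    """Named evaluation reports plus full provenance of one protocol run."""

    protocol: str
    reports: dict[str, MetricReport]
    plan: SplitPlan
    seed: int
    config: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def _stack(pairs: list[SequencePair]):
    return np.stack([p.motion for p in pairs]), np.stack([p.emg for p in pairs])


def _evaluate(est: BaseEmgRegressor, pairs: list[SequencePair],
              condition: str) -> MetricReport:
    X, y = _stack(pairs)
    pred = est.predict(X)
    rep = report([(y[i], pred[i]) for i in range(len(pairs))],
                 metadata={"condition": condition, "n_sequences": len(pairs)})
    return rep


def _fit(est: BaseEmgRegressor, data: ProtocolData, train_pairs, val_pairs, seed: int):
    est = clone(est) if not getattr(est, "warm_start", False) else est
    est.set_params(random_state=seed)
    if not train_pairs:
        raise ValueError("empty training set")
    Xtr, ytr = _stack(train_pairs)
    val = _stack(val_pairs) if val_pairs else None
    est.fit(Xtr, ytr, validation_data=val)
    est.feature_config_ = train_pairs[0].feature_config
    est.scalers_ = {s: {k: sc.to_dict() for k, sc in d.items()}
                    for s, d in data.scalers.items()}
    return est


def run_general(data: ProtocolData | list[SequencePair], estimator: BaseEmgRegressor,
                seed: int, exclude_subject: int | None = None,
                exclude_tasks=(), n_val=None, n_test=None,
                ) -> tuple[BaseEmgRegressor, ProtocolResult]:
    """Train on every subject except the excluded one; evaluate broadly.

    Reports: ``known_motion`` (test repetitions of the training subjects),
    ``new_subject`` (test repetitions of the excluded subject),
    ``new_motion`` (held-out tasks of the training subjects) and
    ``new_motion_new_subject`` (held-out tasks of the excluded subject).
    """
    if not isinstance(data, ProtocolData):
        data = prepare_protocol_data(
            data, heldout_subjects=() if exclude_subject is None else (exclude_subject,),
            heldout_tasks=tuple(exclude_tasks), n_val=n_val, n_test=n_test, seed=seed)
    subjects = data.subjects
    if len(subjects) < 2 and exclude_subject is not None:
        raise ValueError("the general protocol needs at least 2 subjects")
    if exclude_subject is not None and exclude_subject not in subjects:
        raise ValueError(f"excluded subject {exclude_subject} not in the dataset")
    excl_s = data.plan.heldout_subjects
    excl_t = data.plan.heldout_tasks
    train_pairs = data.select(not_subjects=excl_s, not_tasks=excl_t, split="train")
    val_pairs = data.select(not_subjects=excl_s, not_tasks=excl_t, split="val")
    est = _fit(clone(estimator), data, train_pairs, val_pairs,
               _substream(seed, "general"))
    reports = {"known_motion": _evaluate(
        est, data.select(not_subjects=excl_s, not_tasks=excl_t, split="test"),
        "known_motion")}
    if excl_s:
        reports["new_subject"] = _evaluate(
            est, data.select(subjects=excl_s, not_tasks=excl_t, split="test"),
            "new_subject")
    if excl_t:
        nm = data.select(not_subjects=excl_s, tasks=excl_t)
        if nm:
            reports["new_motion"] = _evaluate(est, nm, "new_motion")
        nm_ns = data.select(subjects=excl_s, tasks=excl_t)
        if nm_ns:
            reports["new_motion_new_subject"] = _evaluate(
                est, nm_ns, "new_motion_new_subject")
    result = ProtocolResult("general", reports, data.plan, seed,
                            config={"exclude_subject": exclude_subject,
                                    "exclude_tasks": list(excl_t)})
    return est, result


def run_finetune(general: BaseEmgRegressor, data: ProtocolData, subject: int,
                 seed: int | None, max_epochs: int = 20, learning_rate: float = 1e-4,
                 ) -> tuple[BaseEmgRegressor, ProtocolResult]:
    """Adapt a general model to a new subject by weight-transfer fine-tuning."""
    if seed is None:
        raise ValueError("fine-tuning requires an explicit seed for reproducibility")
    if subject not in data.plan.heldout_subjects:
        raise ValueError(f"subject {subject} was part of the general training set; "
                         "fine-tuning requires an unseen subject")
    ft = transfer_weights(general, fine_tune_lr=learning_rate)
    ft.set_params(max_epochs=max_epochs)
    train_pairs = data.select(subjects=(subject,),
                              not_tasks=data.plan.heldout_tasks, split="train")
    val_pairs = data.select(subjects=(subject,),
                            not_tasks=data.plan.heldout_tasks, split="val")
    ft = _fit(ft, data, train_pairs, val_pairs, _substream(seed, "finetune"))
    reports = {"known_motion": _evaluate(
        ft, data.select(subjects=(subject,), not_tasks=data.plan.heldout_tasks,
                        split="test"), "known_motion")}
    nm = data.select(subjects=(subject,), tasks=data.plan.heldout_tasks)
    if nm:
        reports["new_motion"] = _evaluate(ft, nm, "new_motion")
    return ft, ProtocolResult("finetune", reports, data.plan, seed,
                              config={"subject": subject, "max_epochs": max_epochs,
                                      "learning_rate": learning_rate})


def run_subject_specific(data: ProtocolData, subject: int,
                         estimator: BaseEmgRegressor, seed: int,
                         ) -> tuple[BaseEmgRegressor, ProtocolResult]:
    """Train from scratch on a single subject's training repetitions."""
    if subject not in data.subjects:
        raise ValueError(f"subject {subject} not in the dataset")
    train_pairs = data.select(subjects=(subject,),
                              not_tasks=data.plan.heldout_tasks, split="train")
    val_pairs = data.select(subjects=(subject,),
                            not_tasks=data.plan.heldout_tasks, split="val")
    est = _fit(clone(estimator), data, train_pairs, val_pairs,
               _substream(seed, "subject_specific", subject))
    reports = {"known_motion": _evaluate(
        est, data.select(subjects=(subject,), not_tasks=data.plan.heldout_tasks,
                         split="test"), "known_motion")}
    nm = data.select(subjects=(subject,), tasks=data.plan.heldout_tasks)
    if nm:
        reports["new_motion"] = _evaluate(est, nm, "new_motion")
    return est, ProtocolResult("subject_specific", reports, data.plan, seed,
                               config={"subject": subject})


def run_loo(pairs: list[SequencePair], estimator: BaseEmgRegressor,
            new_motion_tasks, seed: int, n_val=None, n_test=None,
            finetune_epochs: int = 20) -> ProtocolResult:
    """Leave-one-subject-out: hold out each subject in turn and average.

    Per run the general, fine-tuned and subject-specific conditions are
    evaluated; per condition the mean and SD of the channel-averaged scores
    across runs are reported, new-motion scores averaged over the held-out
    tasks.
    """
    subjects = sorted({p.subject for p in pairs})
    if len(subjects) < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    per_run: dict[str, list[float]] = {}
    reports: dict[str, MetricReport] = {}
    for k, held in enumerate(subjects):
        run_seed = _substream(seed, "loo", k)
        data = prepare_protocol_data(pairs, heldout_subjects=(held,),
                                     heldout_tasks=tuple(new_motion_tasks),
                                     n_val=n_val, n_test=n_test, seed=run_seed)
        gen, gres = run_general(data, estimator, run_seed, exclude_subject=held)
        _, fres = run_finetune(gen, data, held, run_seed, max_epochs=finetune_epochs)
        _, sres = run_subject_specific(data, held, estimator, run_seed)
        conditions = {
            "general_known": gres.reports["known_motion"],
            "general_new_subject": gres.reports.get("new_subject"),
            "general_new_motion": gres.reports.get("new_motion_new_subject"),
            "finetuned_known": fres.reports["known_motion"],
            "finetuned_new_motion": fres.reports.get("new_motion"),
            "subject_specific_known": sres.reports["known_motion"],
            "subject_specific_new_motion": sres.reports.get("new_motion"),
        }
        for name, rep in conditions.items():
            if rep is None:
                continue
            per_run.setdefault(name, []).append(rep.average["Zs"])
            reports[f"{name}/run_{held}"] = rep
    summary = {name: {"mean_Zs": float(np.mean(v)), "sd_Zs": float(np.std(v, ddof=1)),
                      "per_run_Zs": list(map(float, v)), "n_runs": len(v)}
               for name, v in per_run.items()}
    return ProtocolResult("loo", reports, SplitPlan(), seed,
                          config={"new_motion_tasks": list(new_motion_tasks)},
                          summary=summary)


def run_repetition_sweep(data: ProtocolData | list[SequencePair],
                         estimator: BaseEmgRegressor, seed: int,
                         counts=(1, 3, 5, 8, 10, 12, 15),
                         exclude_subject=None, exclude_tasks=(),
                         ) -> dict[int, ProtocolResult]:
    """Retrain the general model with a decaying number of train repetitions.

    Validation and test splits stay fixed; at each count only the first
    ``count`` training repetitions of every (subject, task) are kept.
    """
    if not isinstance(data, ProtocolData):
        data = prepare_protocol_data(
            data, heldout_subjects=() if exclude_subject is None else (exclude_subject,),
            heldout_tasks=tuple(exclude_tasks), seed=seed)
    excl_s, excl_t = data.plan.heldout_subjects, data.plan.heldout_tasks
    full_train = data.select(not_subjects=excl_s, not_tasks=excl_t, split="train")
    by_st: dict[tuple[int, int], list[SequencePair]] = {}
    for p in full_train:
        by_st.setdefault((p.subject, p.task), []).append(p)
    max_reps = min(len(v) for v in by_st.values())
    results: dict[int, ProtocolResult] = {}
    for count in counts:
        if count > max_reps:
            raise ValueError(f"requested {count} repetitions but only {max_reps} "
                             "training repetitions are available")
        keep = {p.key for group in by_st.values()
                for p in sorted(group, key=lambda q: q.repetition)[:count]}
        sub = ProtocolData(pairs=data.pairs,
                           plan=SplitPlan(train={k for k in data.plan.train if k in keep},
                                          val=data.plan.val, test=data.plan.test,
                                          heldout_subjects=excl_s, heldout_tasks=excl_t,
                                          seed=data.plan.seed),
                           scalers=data.scalers)
        _, res = run_general(sub, estimator, seed)
        res.config["n_repetitions"] = count
        results[count] = res
    return results


def run_input_ablation(recordings: list[RawRecording], estimator: BaseEmgRegressor,
                       seed: int, configs=("ANG", "VEL", "ACC", "ALL", "EEF", "EEFplus"),
                       exclude_subject=None, exclude_tasks=(),
                       ) -> dict[str, ProtocolResult]:
    """Train one model per input feature configuration on identical splits."""
    results = {}
    for cfg in configs:
        pairs = pairs_from_recordings(recordings, feature_config=cfg)
        _, res = run_general(pairs, estimator, seed, exclude_subject=exclude_subject,
                             exclude_tasks=tuple(exclude_tasks))
        res.config["feature_config"] = cfg
        results[cfg] = res
    return results


def run_added_general(data: ProtocolData | list[SequencePair],
                      estimator: BaseEmgRegressor, seed: int,
                      new_motion_tasks=()) -> ProtocolResult:
    """Train on all subjects at once and compare with per-subject models."""
    if not isinstance(data, ProtocolData):
        data = prepare_protocol_data(data, heldout_tasks=tuple(new_motion_tasks),
                                     seed=seed)
    subjects = data.subjects
    if len(subjects) < 2:
        raise ValueError("the added-general protocol needs at least 2 subjects")
    excl_t = data.plan.heldout_tasks
    train_pairs = data.select(not_tasks=excl_t, split="train")
    val_pairs = data.select(not_tasks=excl_t, split="val")
    added = _fit(clone(estimator), data, train_pairs, val_pairs,
                 _substream(seed, "added_general"))
    reports: dict[str, MetricReport] = {}
    for s in subjects:
        reports[f"added_general/subject_{s}"] = _evaluate(
            added, data.select(subjects=(s,), not_tasks=excl_t, split="test"),
            f"added_general/subject_{s}")
        nm = data.select(subjects=(s,), tasks=excl_t)
        if nm:
            reports[f"added_general_new_motion/subject_{s}"] = _evaluate(
                added, nm, f"added_general_new_motion/subject_{s}")
        _, sres = run_subject_specific(data, s, estimator, seed)
        for name, rep in sres.reports.items():
            reports[f"subject_specific_{name}/subject_{s}"] = rep
    summary = {
        "added_general_mean_Zs": float(np.mean(
            [reports[f"added_general/subject_{s}"].average["Zs"] for s in subjects])),
        "subject_specific_mean_Zs": float(np.mean(
            [reports[f"subject_specific_known_motion/subject_{s}"].average["Zs"]
             for s in subjects])),
    }
    return ProtocolResult("added_general", reports, data.plan, seed,
                          config={"new_motion_tasks": list(new_motion_tasks)},
                          summary=summary)
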
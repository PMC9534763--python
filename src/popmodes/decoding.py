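"""Pseudo-population decoding and pairwise noise correlations.

Decoding assembles pseudo-populations by randomly matching trials across
units that were not recorded together, trains a linear support-vector machine
independently in sliding 200-ms windows (50-ms steps) and reports accuracy
mean +- s.d. over repeated random matchings.  Noise correlation is the
Pearson correlation of mean-subtracted spike counts (100-ms windows) across
trials and windows for simultaneously recorded pairs, subject to the pairing
constraints (distance, trial counts, unique usage of each unit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import ranksums
from sklearn.svm import LinearSVC

from .binning import trial_tensor
from .session import Trial, TrialAlignedSession

__all__ = [
    "DecodingResult",
    "NoiseCorrReport",
    "decode_timecourse",
    "noise_correlation",
    "select_unique_pairs",
]

CONTRASTS = ("stimulus", "choice", "outcome", "epoch4", "reaction_time", "ignore")

_SIGNS = {
    "stimulus": {"CR": 1, "ER": 1, "CL": 0, "EL": 0},
    "choice": {"CR": 1, "EL": 1, "CL": 0, "ER": 0},
    "outcome": {"CR": 1, "CL": 1, "ER": 0, "EL": 0},
}


@dataclass
class DecodingResult:
    contrast: str
    time_s: np.ndarray  # window centers
    accuracy: np.ndarray  # mean over repeats, per window
    accuracy_sd: np.ndarray
    chance: float
    n_units: int
    excluded_units: list[str]


def _window_edges(session: TrialAlignedSession, window_ms: float, step_ms: float):
    t_lo, t_hi = session.epochs.trial_window
    w, s = window_ms / 1000.0, step_ms / 1000.0
    starts = np.arange(t_lo, t_hi - w + 1e-9, s)
    return starts, starts + w


def _counts_by_cell(
    session: TrialAlignedSession,
    unit_ids: list[str],
    cells: dict[str, list[Trial]],
    window_ms: float,
    step_ms: float,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per cell label: spike counts (n_units, n_trials, n_windows)."""
    starts, stops = _window_edges(session, window_ms, step_ms)
    step = step_ms / 1000.0
    nbin_per_win = int(round(window_ms / step_ms))
    t_lo, t_hi = session.epochs.trial_window
    n_fine = int(round((t_hi - t_lo) / step))
    edges = t_lo + np.arange(n_fine + 1) * step
    out = {}
    for cell, trials in cells.items():
        fine = trial_tensor(session, unit_ids, trials, edges).astype(float)
        # sliding-window sums from step-sized bins
        csum = np.concatenate(
            [np.zeros(fine.shape[:2] + (1,)), np.cumsum(fine, axis=2)], axis=2
        )
        n_win = len(starts)
        idx0 = np.arange(n_win)
        idx1 = np.minimum(idx0 + nbin_per_win, n_fine)
        out[cell] = csum[:, :, idx1] - csum[:, :, idx0]
    centers = (starts + stops) / 2
    return out, centers


def _contrast_cells(
    session: TrialAlignedSession, contrast: str
) -> tuple[dict[str, list[Trial]], dict[str, int], float]:
    """Trial cells, cell -> class label, and chance level for a contrast."""
    if contrast in _SIGNS:
        cells = {c: session.trials_of(c, photostim=False) for c in ("CR", "CL", "ER", "EL")}
        return cells, dict(_SIGNS[contrast]), 0.5
    if contrast == "epoch4":
        trials = session.trials_of("CR", "CL", photostim=False)
        return {"correct": trials}, {"correct": 0}, 0.25
    if contrast == "reaction_time":
        trials = [t for t in session.trials_of("CR", "CL", photostim=False) if t.reaction_time_ms]
        trials = sorted(trials, key=lambda t: t.reaction_time_ms)
        third = len(trials) // 3
        return (
            {"fast": trials[:third], "slow": trials[-third:]},
            {"fast": 1, "slow": 0},
            0.5,
        )
    if contrast == "ignore":
        lick = session.trials_of("CR", "CL", "ER", "EL", photostim=False)
        ign = session.trials_of("ignore", photostim=False)
        return {"lick": lick, "ignore": ign}, {"lick": 0, "ignore": 1}, 0.5
    raise ValueError(f"unknown contrast {contrast!r}; choose from {CONTRASTS}")


def decode_timecourse(
    session: TrialAlignedSession,
    contrast: str,
    repeats: int = 20,
    seed: int = 0,
    window_ms: float = 200.0,
    step_ms: float = 50.0,
    train_fraction: float = 0.7,
    C: float = 1.0,
    min_trials_per_cell: int | None = None,
    unit_ids: list[str] | None = None,
) -> DecodingResult:
    """Time-resolved pseudo-population decoding accuracy for a task contrast.

    Stimulus/choice/outcome decoders balance the four trial types so the two
    variables not being decoded are uncorrelated with the decoded one over the
    pseudo-trial set.  Train and test pseudo-trials are assembled from
    disjoint underlying trials of every unit; accuracy is the mean over
    ``repeats`` independent random matchings.
    """
    if min_trials_per_cell is None:
        min_trials_per_cell = 10 if contrast in _SIGNS else 4
    cells, cell_class, chance = _contrast_cells(session, contrast)
    if unit_ids is None:
        unit_ids = session.unit_ids
    # in a pseudo-population every unit contributes its own trials; a unit
    # whose cell lacks trials is excluded (here all units share the session's
    # trial table, so exclusion triggers only on empty cells)
    excluded: list[str] = []
    for cell, trials in cells.items():
        if len(trials) < min_trials_per_cell:
            raise ValueError(
                f"cell {cell!r} has {len(trials)} trials; need >= {min_trials_per_cell}"
            )
    counts, centers = _counts_by_cell(session, unit_ids, cells, window_ms, step_ms)
    n_units = len(unit_ids)
    n_win = centers.size
    epochs = session.epochs
    rng = np.random.default_rng(seed)

    if contrast == "epoch4":
        code = {"presample": 0, "sample": 1, "delay": 2, "response": 3}
        epoch_of_win = np.array([code[epochs.epoch_of(t)] for t in centers])
        w_half = window_ms / 2000.0
        # train only on windows fully inside an epoch; boundary-straddling
        # windows are still evaluated (labeled by their center)
        pure = np.array(
            [
                code[epochs.epoch_of(t - w_half)] == code[epochs.epoch_of(t + w_half - 1e-9)]
                for t in centers
            ]
        )

    acc = np.zeros((repeats, n_win))
    for rep in range(repeats):
        train_X, train_y, test_X, test_y = [], [], [], []
        n_train = min(
            int(np.floor(train_fraction * c.shape[1])) for c in counts.values()
        )
        n_test = min(c.shape[1] - int(np.floor(train_fraction * c.shape[1])) for c in counts.values())
        for cell, tensor in counts.items():
            n_tr = tensor.shape[1]
            # independent trial matching per unit, train/test disjoint per unit
            perm = np.stack([rng.permutation(n_tr) for _ in range(n_units)])
            tr_idx = perm[:, :n_train]
            te_idx = perm[:, n_train : n_train + n_test]
            gather = np.arange(n_units)[:, None]
            train_X.append(np.swapaxes(tensor[gather, tr_idx], 0, 1))  # (n_train, n_units, n_win)
            test_X.append(np.swapaxes(tensor[gather, te_idx], 0, 1))
            train_y.append(np.full(n_train, cell_class[cell]))
            test_y.append(np.full(n_test, cell_class[cell]))
        Xtr = np.concatenate(train_X)
        Xte = np.concatenate(test_X)
        ytr = np.concatenate(train_y)
        yte = np.concatenate(test_y)
        # standardize each unit's counts on training statistics; liblinear
        # penalizes the intercept, so uncentered counts distort the separator.
        # the epoch decoder's signal lives in the differences *between*
        # windows, so it standardizes per unit across windows, not per window
        if contrast == "epoch4":
            mu = Xtr.mean(axis=(0, 2), keepdims=True)
            sd = Xtr.std(axis=(0, 2), keepdims=True) + 1e-9
        else:
            mu = Xtr.mean(axis=0, keepdims=True)
            sd = Xtr.std(axis=0, keepdims=True) + 1e-9
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
        if contrast == "epoch4":
            acc[rep] = _decode_epoch4(Xtr, Xte, epoch_of_win, pure, C, rng)
        else:
            for w in range(n_win):
                clf = LinearSVC(C=C, dual="auto", random_state=0)
                clf.fit(Xtr[:, :, w], ytr)
                acc[rep, w] = float(np.mean(clf.predict(Xte[:, :, w]) == yte))
    return DecodingResult(
        contrast=contrast,
        time_s=centers,
        accuracy=acc.mean(axis=0),
        accuracy_sd=acc.std(axis=0),
        chance=chance,
        n_units=n_units,
        excluded_units=excluded,
    )


def _decode_epoch4(
    Xtr: np.ndarray,
    Xte: np.ndarray,
    epoch_of_win: np.ndarray,
    pure: np.ndarray,
    C: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Four-way epoch classification: one random (epoch-pure) window per epoch
    per training pseudo-trial; evaluated at every window of the test set."""
    feats, labs = [], []
    for ep in range(4):
        wins = np.nonzero((epoch_of_win == ep) & pure)[0]
        if wins.size == 0:
            wins = np.nonzero(epoch_of_win == ep)[0]
        pick = rng.choice(wins, size=Xtr.shape[0])
        feats.append(Xtr[np.arange(Xtr.shape[0]), :, pick])
        labs.append(np.full(Xtr.shape[0], ep))
    clf = LinearSVC(C=C, dual="auto", random_state=0)
    clf.fit(np.concatenate(feats), np.concatenate(labs))
    out = np.zeros(len(epoch_of_win))
    for w in range(len(epoch_of_win)):
        pred = clf.predict(Xte[:, :, w])
        out[w] = float(np.mean(pred == epoch_of_win[w]))
    return out


# ---------------------------------------------------------------------------
# noise correlations
# ---------------------------------------------------------------------------

@dataclass
class NoiseCorrReport:
    pairs: list[tuple[str, str]]
    pair_corr: np.ndarray  # mean over trial types per pair
    within_mask: np.ndarray  # bool per pair
    rank_sum_p: float
    epoch: str

    @property
    def within(self) -> np.ndarray:
        return self.pair_corr[self.within_mask]

    @property
    def across(self) -> np.ndarray:
        return self.pair_corr[~self.within_mask]


def select_unique_pairs(
    candidates: list[tuple[str, str]], seed: int = 0
) -> list[tuple[str, str]]:
    """Greedy maximal matching in randomized order: each unit in <= 1 pair."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))
    used: set[str] = set()
    out = []
    for i in order:
        a, b = candidates[i]
        if a in used or b in used:
            continue
        used.update((a, b))
        out.append((a, b))
    return out


def noise_correlation(
    session: TrialAlignedSession,
    labels: dict[str, int],
    epoch: str = "delay",
    trial_types: tuple[str, ...] = ("CR", "CL"),
    window_ms: float = 100.0,
    min_distance_um: float = 100.0,
    min_trials: int = 10,
    seed: int = 0,
) -> NoiseCorrReport:
    """Within- versus across-cluster noise correlations.

    Pairs must be more than ``min_distance_um`` apart along the probe, have at
    least ``min_trials`` trials of each trial type, and each unit enters at
    most one pair (greedy randomized maximal matching).  For each pair and
    trial type, spike counts in ``window_ms`` windows of the epoch have the
    per-window trial-type mean removed and are correlated across trials and
    windows; a pair's value averages the trial types.  The within/across
    comparison uses a two-sided Wilcoxon rank-sum test.
    """
    unit_ids = [u for u in session.unit_ids if u in labels]
    for tt in trial_types:
        if len(session.trials_of(tt, photostim=False)) < min_trials:
            raise ValueError(f"fewer than {min_trials} trials of type {tt!r}")
    depth = {u.unit_id: u.depth_um for u in session.units}
    cands = [
        (a, b)
        for i, a in enumerate(unit_ids)
        for b in unit_ids[i + 1 :]
        if abs(depth[a] - depth[b]) > min_distance_um
    ]
    pairs = select_unique_pairs(cands, seed=seed)
    lo, hi = session.epochs.window(epoch)
    w = window_ms / 1000.0
    n_w = int((hi - lo) / w)
    edges = lo + np.arange(n_w + 1) * w
    uid_index = {u: i for i, u in enumerate(unit_ids)}

    per_type = []
    for tt in trial_types:
        trials = session.trials_of(tt, photostim=False)
        tens = trial_tensor(session, unit_ids, trials, edges).astype(float)
        tens -= tens.mean(axis=1, keepdims=True)  # remove per-window type mean
        per_type.append(tens.reshape(len(unit_ids), -1))

    kept_pairs, vals, within = [], [], []
    for a, b in pairs:
        ia, ib = uid_index[a], uid_index[b]
        rs = []
        for tens in per_type:
            xa, xb = tens[ia], tens[ib]
            if xa.std() == 0 or xb.std() == 0:
                continue
            rs.append(float(np.corrcoef(xa, xb)[0, 1]))
        if not rs:
            continue
        kept_pairs.append((a, b))
        vals.append(float(np.mean(rs)))
        within.append(labels[a] == labels[b])
    vals = np.asarray(vals)
    within = np.asarray(within, bool)
    if within.any() and (~within).any():
        p = float(ranksums(vals[within], vals[~within]).pvalue)
    else:
        warnings.warn("need both within- and across-cluster pairs for the test", stacklevel=2)
        p = float("nan")
    return NoiseCorrReport(
        pairs=kept_pairs, pair_corr=vals, within_mask=within, rank_sum_p=p, epoch=epoch
    )
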
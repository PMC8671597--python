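"""F0-classifier model objects.

The central fitted object of the package, organized in the model/results
style of statistical modelling libraries: :class:`F0Classifier` is built from
a labeled dataset plus an :class:`~pitchsim.nnet.ArchitectureSpec`;
``fit()`` runs softmax cross-entropy training with Adam (batch 64, learning
rate 1e-4 by default), evaluating a held-out validation split at a fixed
interval, stopping when accuracy stops improving by at least 0.5 percentage
points per evaluation, and aborting networks stuck below 5% accuracy at
10,000 steps.  The returned :class:`F0ClassifierResults` carries the trained
network, the per-evaluation accuracy trace, a ``summary()`` table, and the
windowed F0-prediction surface used by the psychophysics module.

Dropout is active during evaluation as well as training, so predictions are
stochastic; ``eval_passes`` controls how many passes are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio import AudioError
from .dataset import Dataset, F0BinGrid
from .nnet import Adam, ArchitectureSpec, Network, softmax, softmax_xent

__all__ = [
    "TrainConfig",
    "F0Classifier",
    "F0ClassifierResults",
    "predict_f0",
    "window_mask",
    "median_pct_error",
    "uniform_random_estimator_error",
    "LearnableFrontendSpec",
    "learnable_frontend_spec",
    "best_frequency",
]


@dataclass
class TrainConfig:
    """Optimization protocol parameters (full-scale defaults)."""

    batch_size: int = 64
    learning_rate: float = 1e-4
    val_fraction: float = 0.2
    eval_interval: int = 5000
    stop_improvement: float = 0.005  # 0.5% classification accuracy
    stop_baseline: str = "previous"  # or "best"
    abort_accuracy: float = 0.05
    abort_step: int = 10000
    max_steps: int = 100000
    dropout_eval_passes: int = 1

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise AudioError("val_fraction must be in (0, 1)")
        if min(self.batch_size, self.learning_rate, self.eval_interval) <= 0:
            raise AudioError("training parameters must be positive")

    @classmethod
    def desk_scale(cls, **kw) -> "TrainConfig":
        """Reduced protocol for single-CPU runs: a higher learning rate and
        a few hundred steps; the plateau rule is disabled because the tiny
        validation split makes per-evaluation accuracy too noisy for it."""
        kw.setdefault("learning_rate", 1e-3)
        kw.setdefault("eval_interval", 100)
        kw.setdefault("max_steps", 800)
        kw.setdefault("stop_improvement", -1.0)
        kw.setdefault("abort_step", 10**9)
        kw.setdefault("dropout_eval_passes", 2)
        return cls(**kw)


# ---------------------------------------------------------------------------
# Windowed prediction
# ---------------------------------------------------------------------------

def window_mask(grid: F0BinGrid, center: float, octaves: float) -> np.ndarray:
    lo = center * 2.0 ** (-octaves / 2.0)
    hi = center * 2.0 ** (octaves / 2.0)
    mask = (grid.centers >= lo) & (grid.centers <= hi)
    if not mask.any():
        raise AudioError("empty prediction window")
    return mask


def predict_f0(scores: np.ndarray, grid: F0BinGrid, center: float,
               octaves: float) -> np.ndarray:
    """Windowed argmax decoding: the winning in-window bin's geometric center.

    ``scores`` is (..., n_bins).  Ties resolve to the lowest bin index;
    the 2AFC protocol adds seeded tie noise downstream.
    """
    scores = np.asarray(scores)
    mask = window_mask(grid, center, octaves)
    masked = np.where(mask, scores, -np.inf)
    idx = np.argmax(masked, axis=-1)
    return grid.centers[idx]


def median_pct_error(pred_f0: np.ndarray, true_f0: np.ndarray) -> float:
    return float(np.median(100.0 * np.abs(pred_f0 - true_f0) / true_f0))


def uniform_random_estimator_error(grid: F0BinGrid, rng: np.random.Generator,
                                   true_f0s: np.ndarray,
                                   n_draws: int = 10000) -> float:
    """Median %F0 error of a predictor uniform on the grid's log-F0 range."""
    t = rng.choice(np.asarray(true_f0s, dtype=float), size=n_draws)
    p = np.exp(rng.uniform(np.log(grid.edges[0]), np.log(grid.edges[-1]),
                           size=n_draws))
    return median_pct_error(p, t)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class F0Classifier:
    """Convolutional F0-classification model bound to its training data.

    Parameters
    ----------
    X : ndarray, (n, n_fibers, n_timesteps)
        Input representations (nervegrams).
    y : ndarray of int
        F0 bin labels.
    grid : F0BinGrid
        The label grid (decodes classes back to Hz).
    spec : ArchitectureSpec, optional
        Drawn with :func:`pitchsim.nnet.sample_architecture` if omitted.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, grid: F0BinGrid,
                 spec: ArchitectureSpec | None = None,
                 seed: int | None = None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3 or len(X) != len(y):
            raise AudioError("X must be (n, fibers, timesteps) matching y")
        self.X, self.y, self.grid = X, y, grid
        rng = np.random.default_rng(seed)
        if spec is None:
            from .nnet import sample_architecture

            spec = sample_architecture(rng, X.shape[1:], grid.n_bins)
        if spec.n_classes != grid.n_bins:
            raise AudioError("spec output classes must match the bin grid")
        self.spec = spec
        # affine input map applied before the network: (x - center) / scale
        self.input_center = 0.0
        self.input_scale = 1.0
        self._init_rng = rng

    def normalize_input(self, rates: np.ndarray) -> np.ndarray:
        """Map raw firing rates onto the network's input scale."""
        return (np.asarray(rates, dtype=np.float32) - self.input_center) \
            / self.input_scale

    @classmethod
    def from_dataset(cls, ds: Dataset, spec: ArchitectureSpec | None = None,
                     seed: int | None = None) -> "F0Classifier":
        first = ds.examples[0].input
        if not hasattr(first, "rates"):
            raise AudioError("dataset examples must carry nervegrams")
        X = np.stack([e.input.rates for e in ds.examples])
        center = float(X.mean())
        scale = max(float(X.std()), 1e-9)
        X = (X - center) / scale  # standardized rates
        y = np.array([e.bin_index for e in ds.examples])
        obj = cls(X, y, ds.grid, spec, seed)
        obj.input_center, obj.input_scale = center, scale
        return obj

    def fit(self, cfg: TrainConfig | None = None,
            seed: int = 0) -> "F0ClassifierResults":
        cfg = cfg or TrainConfig()
        rng = np.random.default_rng(seed)
        net = Network(self.spec, rng)
        opt = Adam(net.params, lr=cfg.learning_rate)
        n = len(self.X)
        perm = rng.permutation(n)
        n_val = max(1, int(round(cfg.val_fraction * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        history, stop_reason = [], "max_steps"
        best_acc = prev_acc = -np.inf
        step = 0
        order = rng.permutation(train_idx)
        pos = 0
        while step < cfg.max_steps:
            if pos + cfg.batch_size > len(order):
                order = rng.permutation(train_idx)
                pos = 0
            batch = order[pos:pos + cfg.batch_size]
            pos += cfg.batch_size
            logits = net.forward(self.X[batch], train=True, rng=rng)
            loss, grad = softmax_xent(logits, self.y[batch])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"divergent loss ({loss}) at step {step}")
            net.backward(grad)
            opt.step(net.grads)
            step += 1
            if step % cfg.eval_interval == 0 or step == cfg.max_steps:
                acc, med_err = self._evaluate(net, val_idx, cfg, rng)
                history.append({"step": step, "val_accuracy": acc,
                                "median_pct_error": med_err, "loss": loss})
                baseline = prev_acc if cfg.stop_baseline == "previous" else best_acc
                improved = acc - baseline
                best_acc = max(best_acc, acc)
                prev_acc = acc
                if step >= cfg.abort_step and acc < cfg.abort_accuracy:
                    stop_reason = "aborted_low_accuracy"
                    break
                if len(history) > 1 and improved < cfg.stop_improvement:
                    stop_reason = "accuracy_plateau"
                    break
        return F0ClassifierResults(self, net, pd.DataFrame(history),
                                   stop_reason, cfg)

    def _evaluate(self, net, idx, cfg, rng, batch: int = 256):
        scores = []
        for k in range(0, len(idx), batch):
            sl = idx[k:k + batch]
            s = np.zeros((len(sl), self.grid.n_bins), dtype=np.float64)
            for _ in range(cfg.dropout_eval_passes):
                s += softmax(net.forward(self.X[sl], train=False, rng=rng))
            scores.append(s / cfg.dropout_eval_passes)
        scores = np.concatenate(scores)
        pred_bin = scores.argmax(axis=-1)
        acc = float(np.mean(pred_bin == self.y[idx]))
        med = median_pct_error(self.grid.centers[pred_bin],
                               self.grid.centers[self.y[idx]])
        return acc, med


class F0ClassifierResults:
    """Trained-network results: history, estimator surface, summary."""

    def __init__(self, model: F0Classifier, network: Network,
                 history: pd.DataFrame, stop_reason: str, cfg: TrainConfig):
        self.model = model
        self.network = network
        self.history = history
        self.stop_reason = stop_reason
        self.train_config = cfg

    @property
    def final_accuracy(self) -> float:
        return float(self.history["val_accuracy"].iloc[-1])

    @property
    def final_median_error(self) -> float:
        return float(self.history["median_pct_error"].iloc[-1])

    def class_scores(self, X: np.ndarray, rng: np.random.Generator,
                     passes: int | None = None, batch: int = 256) -> np.ndarray:
        """Softmax class probabilities, averaged over dropout passes."""
        X = np.asarray(X, dtype=np.float32)
        passes = passes or self.train_config.dropout_eval_passes
        out = []
        for k in range(0, len(X), batch):
            s = np.zeros((len(X[k:k + batch]), self.model.grid.n_bins))
            for _ in range(passes):
                s += softmax(self.network.forward(X[k:k + batch], train=False,
                                                  rng=rng))
            out.append(s / passes)
        return np.concatenate(out)

    def predict_f0(self, X: np.ndarray, center: float, octaves: float,
                   rng: np.random.Generator) -> np.ndarray:
        scores = self.class_scores(X, rng)
        return predict_f0(scores, self.model.grid, center, octaves)

    def layer_activations(self, X: np.ndarray, rng: np.random.Generator) -> dict:
        """Named per-layer activations: the ReLU output after each conv
        layer (and the intermediate FC layer), plus the final FC logits."""
        logits, acts = self.network.forward(np.asarray(X, dtype=np.float32),
                                            train=False, rng=rng, collect=True)
        names = self.network.layer_names()
        out = dict(zip(names[:-1], acts))
        out["fc_output"] = logits
        return out

    def save(self, directory) -> None:
        """Persist the trained network: parameters and batch-norm running
        statistics as NPZ, a JSON architecture manifest, history as CSV."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        arrays = {f"param_{i}": p for i, p in enumerate(self.network.params)}
        from .nnet import BatchNorm

        for i, layer in enumerate(self.network.layers):
            if isinstance(layer, BatchNorm):
                arrays[f"bn{i}_mean"] = layer.run_mean
                arrays[f"bn{i}_var"] = layer.run_var
                arrays[f"bn{i}_n"] = np.array(layer.n_updates)
        np.savez(d / "checkpoint.npz", **arrays)
        manifest = {"architecture": asdict(self.model.spec),
                    "input_center": self.model.input_center,
                    "input_scale": self.model.input_scale,
                    "stop_reason": self.stop_reason,
                    "grid": {"f_min": self.model.grid.f_min,
                             "f_max": self.model.grid.f_max,
                             "bin_width": self.model.grid.bin_width}}
        (d / "architecture.json").write_text(json.dumps(manifest, indent=1))
        self.history.to_csv(d / "history.csv", index=False)

    @classmethod
    def load(cls, directory) -> "F0ClassifierResults":
        """Rebuild results from a checkpoint directory (weights, manifest,
        history); the data arrays are not restored."""
        import json
        from pathlib import Path

        from .dataset import F0BinGrid
        from .nnet import ArchitectureSpec, BatchNorm, Network

        d = Path(directory)
        manifest = json.loads((d / "architecture.json").read_text())
        arch = manifest["architecture"]
        arch["input_shape"] = tuple(arch["input_shape"])
        arch["kernel_sizes"] = [tuple(k) for k in arch["kernel_sizes"]]
        arch["pool_strides"] = [tuple(s) for s in arch["pool_strides"]]
        spec = ArchitectureSpec(**arch)
        grid = F0BinGrid(**manifest["grid"])
        net = Network(spec, np.random.default_rng(0))
        data = np.load(d / "checkpoint.npz")
        for i, p in enumerate(net.params):
            p[...] = data[f"param_{i}"]
        for i, layer in enumerate(net.layers):
            if isinstance(layer, BatchNorm):
                layer.run_mean = data[f"bn{i}_mean"]
                layer.run_var = data[f"bn{i}_var"]
                layer.n_updates = int(data[f"bn{i}_n"])
        model = object.__new__(F0Classifier)
        model.X = model.y = None
        model.grid, model.spec = grid, spec
        model.input_center = manifest.get("input_center", 0.0)
        model.input_scale = manifest["input_scale"]
        history = pd.read_csv(d / "history.csv")
        return cls(model, net, history, manifest["stop_reason"],
                   TrainConfig())

    def summary(self) -> str:
        s = self.model.spec
        lines = [
            "F0 classifier results",
            "=" * 44,
            f"conv layers:        {s.n_conv_layers}",
            f"kernel counts:      {s.kernel_counts}",
            f"kernel sizes:       {s.kernel_sizes}",
            f"pool strides:       {s.pool_strides}",
            f"penultimate FC:     {s.fc_width}",
            f"output classes:     {s.n_classes}",
            f"parameters:         {sum(p.size for p in self.network.params)}",
            f"training steps:     {int(self.history['step'].iloc[-1])}",
            f"stop reason:        {self.stop_reason}",
            f"val accuracy:       {self.final_accuracy:.3f}",
            f"median %F0 error:   {self.final_median_error:.2f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Learnable cochlear front end (description + forward transform)
# ---------------------------------------------------------------------------

@dataclass
class LearnableFrontendSpec:
    """Learnable replacement for the hardwired cochlea: 100 one-dimensional
    801-tap filters applied by valid convolution to 75 ms of 32 kHz audio,
    half-wave rectified and resampled to 20 kHz, yielding 100 x 1000."""

    n_filters: int = 100
    n_taps: int = 801
    input_duration: float = 0.075
    sample_rate: float = 32000.0
    output_rate: float = 20000.0

    @property
    def input_samples(self) -> int:
        return int(round(self.input_duration * self.sample_rate))

    @property
    def valid_output_samples(self) -> int:
        return self.input_samples - self.n_taps + 1

    def apply(self, audio: np.ndarray, kernels: np.ndarray) -> np.ndarray:
        """Forward transform of one audio snippet through a kernel bank."""
        from scipy.signal import resample_poly

        audio = np.asarray(audio, dtype=float)
        if len(audio) != self.input_samples:
            raise AudioError(
                f"expected {self.input_samples} samples "
                f"({self.input_duration * 1000:.0f} ms at {self.sample_rate:.0f} Hz)")
        if kernels.shape != (self.n_filters, self.n_taps):
            raise AudioError("kernel bank shape mismatch")
        out = np.stack([np.convolve(audio, k[::-1], mode="valid")
                        for k in kernels])
        out = np.maximum(out, 0.0)
        return resample_poly(out, int(self.output_rate), int(self.sample_rate),
                             axis=-1)


def learnable_frontend_spec() -> LearnableFrontendSpec:
    return LearnableFrontendSpec()


def best_frequency(kernel: np.ndarray, sample_rate: float = 32000.0) -> float:
    """Best frequency of a front-end filter: argmax of its magnitude transfer
    function.  Raises on an all-zero kernel."""
    kernel = np.asarray(kernel, dtype=float)
    if not np.any(kernel):
        raise AudioError("best frequency undefined for an all-zero kernel")
    n_fft = max(4096, len(kernel))
    mag = np.abs(np.fft.rfft(kernel, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, 1.0 / sample_rate)
    return float(freqs[np.argmax(mag)])
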
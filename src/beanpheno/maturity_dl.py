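"""CNN-LSTM relative-maturity regressor.

Each plot is observed as a short sequence of RGB images (one per flight).  A
time-distributed stack of four convolutional layers (ReLU, 2x2 max pool after
each, Xavier-initialized) embeds every flight image into a feature vector;
dropout is applied to those features, an LSTM consumes the sequence, and a
single linear neuron regresses maturity in days after planting.  Training
minimizes a Huber loss (quadratic within sigma days, linear beyond), which
keeps a few badly-scored plots from dominating the fit.  Optionally a small
dense subnetwork embeds cumulative growing degree days (GDD) at each flight
and its output is concatenated with the per-flight CNN features before the
LSTM, letting the model see how much thermal time each environment had
accumulated.

The network is implemented directly in NumPy (see :mod:`._nn`) with
hand-written backpropagation and an Adam optimizer; runs are deterministic
given the configured seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ._nn import LSTM, Adam, Conv2D, Dense, Dropout, MaxPool2x2, ReLU
from .geoplots import FlightRecord, PlotImageSeries


@dataclass
class ModelConfig:
    image_size: tuple[int, int] = (64, 256)          # (height, width)
    filters: tuple[int, int, int, int] = (16, 32, 64, 128)
    kernel: int = 3
    pool_stride: int = 2
    dropout: float = 0.2
    lstm_units: int = 256
    learning_rate: float = 1e-3
    decay: float = 1e-3                              # per-epoch learning-rate decay
    batch_size: int = 16
    epochs: int = 200
    huber_sigma: float = 0.1
    seed: int = 0
    use_gdd: bool = False
    gdd_units: int = 8
    gdd_scale: float = 1000.0                        # cumulative GDD / scale fed to the net

    def __post_init__(self) -> None:
        if len(self.filters) != 4:
            raise ValueError("exactly 4 convolutional layers are expected")
        if any(f <= 0 for f in self.filters):
            raise ValueError("filter counts must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.pool_stride != 2:
            raise ValueError("only pool stride 2 is supported")
        h, w = self.image_size
        if h % 16 or w % 16:
            raise ValueError(
                f"image size {self.image_size} is not divisible by 2^4 for 4 pool stages")


def huber_loss(predicted, observed, sigma: float = 0.1) -> float:
    """Mean Huber loss: 0.5 r^2 for |r| <= sigma, sigma(|r| - 0.5 sigma) beyond."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} vs {observed.shape}")
    r = predicted - observed
    a = np.abs(r)
    per = np.where(a <= sigma, 0.5 * r * r, sigma * (a - 0.5 * sigma))
    return float(per.mean())


def _huber_grad(predicted, observed, sigma):
    r = predicted - observed
    return np.clip(r, -sigma, sigma) / r.size


@dataclass
class GDDSeries:
    daily_gdd: np.ndarray            # per day after planting, day 1..N
    tbase: float
    flight_days: np.ndarray          # days after planting sampled
    cumulative: np.ndarray           # cumulative GDD at each flight day

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cumulative) < 0):
            raise ValueError("cumulative GDD must be non-decreasing")


def cumulative_gdd(tmin, tmax, flights: list[FlightRecord] | np.ndarray,
                   tbase: float = 10.0, dates=None) -> GDDSeries:
    """Accumulate daily growing degree days and sample them at flight days.

    ``tmin``/``tmax`` are daily series starting the day after planting.  Daily
    GDD = max(0, (tmax + tmin)/2 - tbase).  ``dates``, when given, must be
    consecutive calendar days (gaps are an error).
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if tmin.shape != tmax.shape:
        raise ValueError("tmin and tmax must align")
    if dates is not None:
        d = np.asarray(dates, dtype="datetime64[D]")
        if np.any(np.diff(d).astype(int) != 1):
            raise ValueError("daily temperature series has gaps")
        if d.size != tmin.size:
            raise ValueError("dates and temperatures must align")
    if isinstance(flights, (list, tuple)) and flights and isinstance(flights[0], FlightRecord):
        flight_days = np.array([f.days_after_planting for f in flights], dtype=int)
    else:
        flight_days = np.asarray(flights, dtype=int)
    if flight_days.max() > tmin.size:
        raise ValueError(
            f"daily series covers {tmin.size} days but a flight is at day "
            f"{flight_days.max()} after planting")
    daily = np.maximum(0.0, (tmax + tmin) / 2.0 - tbase)
    cum = np.concatenate([[0.0], np.cumsum(daily)])
    return GDDSeries(daily_gdd=daily, tbase=tbase, flight_days=flight_days,
                     cumulative=cum[flight_days])


class CNNLSTM:
    """The assembled network; build through :func:`build_cnn_lstm`."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        h, w = config.image_size
        chans = (3,) + tuple(config.filters)
        self.convs = []
        for cin, f in zip(chans[:-1], chans[1:]):
            self.convs.append((Conv2D(rng, cin, f, config.kernel), ReLU(), MaxPool2x2()))
        self.feature_dim = (h // 16) * (w // 16) * config.filters[-1]
        self.dropout = Dropout(config.dropout)
        lstm_in = self.feature_dim + (config.gdd_units if config.use_gdd else 0)
        self.gdd_dense = Dense(rng, 1, config.gdd_units) if config.use_gdd else None
        self.gdd_relu = ReLU() if config.use_gdd else None
        self.lstm = LSTM(rng, lstm_in, config.lstm_units)
        self.head = Dense(rng, config.lstm_units, 1)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        # label standardization (set by train); the head regresses z-scores
        # so day-scale targets are reachable within a few hundred Adam steps
        self.label_mean = 0.0
        self.label_std = 1.0

    # -- parameters -------------------------------------------------------
    def _layers_with_params(self):
        layers = [conv for conv, _, _ in self.convs]
        if self.gdd_dense is not None:
            layers.append(self.gdd_dense)
        layers += [self.lstm, self.head]
        return layers

    @property
    def params(self):
        return [p for layer in self._layers_with_params() for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self._layers_with_params() for g in layer.grads]

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    # -- forward / backward ----------------------------------------------
    @staticmethod
    def _scale_images(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if np.issubdtype(x.dtype, np.integer) or x.max(initial=0.0) > 1.5:
            return (x / 255.0).astype(np.float32)
        return x.astype(np.float32)

    def _check_stack(self, x: np.ndarray) -> None:
        if x.ndim != 5 or x.shape[4] != 3:
            raise ValueError(f"expected a (plots, flights, H, W, 3) block, got {x.shape}")
        if x.shape[2:4] != self.config.image_size:
            raise ValueError(
                f"image size {x.shape[2:4]} does not match model {self.config.image_size}")

    def _prepare_gdd(self, gdd, n_plots: int, n_flights: int) -> np.ndarray:
        if gdd is None:
            raise ValueError("model was built with use_gdd=True but no GDD given")
        if isinstance(gdd, GDDSeries):
            gdd = gdd.cumulative
        g = np.asarray(gdd, dtype=np.float32) / self.config.gdd_scale
        if g.ndim == 1:
            if g.size != n_flights:
                raise ValueError("one cumulative GDD value per flight is required")
            g = np.broadcast_to(g, (n_plots, n_flights)).copy()
        elif g.shape != (n_plots, n_flights):
            raise ValueError(f"GDD block must be (plots, flights), got {g.shape}")
        return g

    def forward(self, x: np.ndarray, gdd=None, train: bool = False) -> np.ndarray:
        """x: (plots, flights, H, W, 3) -> per-plot prediction (plots,)."""
        self._check_stack(x)
        N, T, H, W, _ = x.shape
        z = self._scale_images(x).reshape(N * T, H, W, 3)
        for conv, relu, pool in self.convs:
            z = pool.forward(relu.forward(conv.forward(z)))
        feats = z.reshape(N * T, -1)
        feats = self.dropout.forward(feats, self._dropout_rng, train=train)
        feats = feats.reshape(N, T, -1)
        if self.gdd_dense is not None:
            g = self._prepare_gdd(gdd, N, T)
            emb = self.gdd_relu.forward(
                self.gdd_dense.forward(g.reshape(N * T, 1)))
            feats = np.concatenate([feats, emb.reshape(N, T, -1)], axis=2)
        h_last = self.lstm.forward(feats)
        out = self.head.forward(h_last)
        self._fwd_shape = (N, T)
        return out[:, 0] * self.label_std + self.label_mean

    def backward(self, dout: np.ndarray) -> None:
        """Backpropagate d(loss)/d(prediction in days)."""
        N, T = self._fwd_shape
        dout = dout * self.label_std
        dh = self.head.backward(dout[:, None].astype(np.float32))
        dfeats = self.lstm.backward(dh)
        if self.gdd_dense is not None:
            demb = dfeats[:, :, self.feature_dim:]
            dfeats = dfeats[:, :, :self.feature_dim]
            self.gdd_dense.backward(
                self.gdd_relu.backward(demb.reshape(N * T, -1)))
        dz = self.dropout.backward(dfeats.reshape(N * T, -1))
        h, w = self.config.image_size
        dz = dz.reshape(N * T, h // 16, w // 16, self.config.filters[-1])
        for conv, relu, pool in reversed(self.convs):
            dz = conv.backward(relu.backward(pool.backward(dz)))

    def predict(self, stack, gdd=None) -> np.ndarray:
        """Per-plot maturity (days after planting) for a stack or raw block."""
        x = stack.data.transpose(1, 0, 2, 3, 4) if isinstance(stack, PlotImageSeries) else stack
        return self.forward(np.asarray(x), gdd=gdd, train=False).astype(float)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        np.savez(path, _config=np.frombuffer(
            repr(asdict(self.config)).encode(), dtype=np.uint8),
            _label_norm=np.array([self.label_mean, self.label_std]), **arrays)

    @classmethod
    def load(cls, path) -> "CNNLSTM":
        import ast
        with np.load(path) as data:
            cfg_dict = ast.literal_eval(bytes(data["_config"]).decode())
            for key in ("image_size", "filters"):
                cfg_dict[key] = tuple(cfg_dict[key])
            model = cls(ModelConfig(**cfg_dict))
            model.label_mean, model.label_std = data["_label_norm"]
            for i, p in enumerate(model.params):
                p[...] = data[f"p{i}"]
        return model


def build_cnn_lstm(config: ModelConfig) -> CNNLSTM:
    """Construct the model with Xavier-initialized weights (seeded)."""
    return CNNLSTM(config)


@dataclass
class TrainResult:
    train_loss: list[float]
    val_loss: list[float]
    final_train_mae: float
    final_train_mse: float
    final_test_mae: float | None
    final_test_mse: float | None
    seed: int
    config: ModelConfig


def _as_block(stack) -> np.ndarray:
    if isinstance(stack, PlotImageSeries):
        return stack.data.transpose(1, 0, 2, 3, 4)  # -> (plots, flights, H, W, 3)
    return np.asarray(stack)


def train(model: CNNLSTM, stack, labels, config: ModelConfig | None = None,
          gdd=None, val_data=None, test_data=None,
          stop_at_train_mae: float | None = None, check_every: int = 10,
          collapse_check: tuple[int, float] | None = None) -> TrainResult:
    """Adam minimization of the Huber loss on (stack, labels).

    Labels are standardized inside the model (the head regresses z-scores,
    predictions come back in days), which keeps day-scale targets reachable.
    ``val_data``/``test_data`` are optional (block, labels[, gdd]) tuples; the
    validation loss is recorded per epoch, the test MAE/MSE at the end.
    ``stop_at_train_mae`` stops early once the full-train MAE (checked every
    ``check_every`` epochs) reaches the target.  ``collapse_check=(epoch,
    min_std)`` aborts a run whose predictions have collapsed to a constant
    (spread below ``min_std`` days at that epoch) - the symptom of the
    median-prediction stall an L1-like loss can fall into on tiny sets; see
    :func:`train_with_restarts`.  Raises on a non-finite loss, naming the
    epoch.
    """
    config = config or model.config
    x = _as_block(stack)
    y = np.asarray(labels, dtype=np.float32)
    if x.shape[0] != y.size:
        raise ValueError(f"{x.shape[0]} plots but {y.size} labels")
    if config.epochs > 0 and y.size > 1:
        model.label_mean = float(y.mean())
        model.label_std = float(max(y.std(), 1e-6))
    rng = np.random.default_rng(config.seed + 2)
    n = x.shape[0]
    train_hist: list[float] = []
    val_hist: list[float] = []
    optimizer = Adam(model.params, lr=config.learning_rate)
    gdd_arr = gdd
    for epoch in range(config.epochs):
        lr = config.learning_rate / (1.0 + config.decay * epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            gb = None
            if model.gdd_dense is not None:
                g = model._prepare_gdd(gdd_arr, n, x.shape[1])
                gb = g[idx] * config.gdd_scale  # _prepare_gdd rescales again
            pred = model.forward(x[idx], gdd=gb, train=True)
            loss = huber_loss(pred, y[idx], config.huber_sigma)
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            model.backward(_huber_grad(pred, y[idx], config.huber_sigma))
            optimizer.step(model.grads, lr=lr)
            epoch_loss += loss * idx.size
        train_hist.append(epoch_loss / n)
        if val_data is not None:
            vx, vy = val_data[0], np.asarray(val_data[1], dtype=float)
            vg = val_data[2] if len(val_data) > 2 else gdd_arr
            vpred = model.forward(_as_block(vx),
                                  gdd=vg if model.gdd_dense is not None else None)
            val_hist.append(huber_loss(vpred, vy, config.huber_sigma))
        need_stop_check = (stop_at_train_mae is not None
                           and (epoch + 1) % check_every == 0)
        need_collapse_check = (collapse_check is not None
                               and epoch + 1 == collapse_check[0])
        if need_stop_check or need_collapse_check:
            full = model.forward(
                x, gdd=(model._prepare_gdd(gdd_arr, n, x.shape[1]) * config.gdd_scale
                        if model.gdd_dense is not None else None))
            if need_stop_check and np.abs(full - y).mean() < stop_at_train_mae:
                break
            if need_collapse_check and full.std() < collapse_check[1]:
                break
    pred = model.forward(x, gdd=(model._prepare_gdd(gdd_arr, n, x.shape[1])
                                 * config.gdd_scale if model.gdd_dense is not None else None))
    resid = pred - y
    test_mae = test_mse = None
    if test_data is not None:
        tx, ty = test_data[0], np.asarray(test_data[1], dtype=float)
        tg = test_data[2] if len(test_data) > 2 else gdd_arr
        tpred = model.forward(_as_block(tx),
                              gdd=tg if model.gdd_dense is not None else None)
        test_mae = float(np.abs(tpred - ty).mean())
        test_mse = float(((tpred - ty) ** 2).mean())
    return TrainResult(train_loss=train_hist, val_loss=val_hist,
                       final_train_mae=float(np.abs(resid).mean()),
                       final_train_mse=float((resid ** 2).mean()),
                       final_test_mae=test_mae, final_test_mse=test_mse,
                       seed=config.seed, config=config)


def predict(model: CNNLSTM, stack, gdd=None) -> np.ndarray:
    return model.predict(stack, gdd=gdd)


def train_with_restarts(stack, labels, config: ModelConfig,
                        target_train_mae: float = 0.8,
                        max_attempts: int = 6,
                        attempt_epochs: int = 80,
                        collapse_check: tuple[int, float] = (20, 0.5),
                        gdd=None) -> tuple[CNNLSTM, TrainResult]:
    """Restarts over seeds and init gains around the median-prediction stall.

    On very small training sets the near-L1 Huber objective has a symmetric
    trap: predictions collapse to the label median and per-sample gradients
    cancel through the shared weights.  Whether an initialization escapes
    depends unpredictably on the data/init pair, and different init scales
    escape on different sets, so attempts cycle through three
    symmetry-breaking variants - baseline, LSTM input weights x8, head
    weights x8 - before bumping the seed.  A collapsed attempt is recognized
    early by its near-constant predictions and abandoned after
    ``collapse_check[0]`` epochs; the loop returns the first attempt
    reaching ``target_train_mae``, else the best attempt seen.  Fully
    deterministic given ``config.seed``.
    """
    from dataclasses import replace as _replace

    gains = ((1.0, 1.0), (8.0, 1.0), (1.0, 8.0))   # (LSTM Wx, head W)
    best: tuple[CNNLSTM, TrainResult] | None = None
    for attempt in range(max_attempts):
        wx_gain, head_gain = gains[attempt % len(gains)]
        cfg = _replace(config, seed=config.seed + 101 * (attempt // len(gains)),
                       epochs=attempt_epochs)
        model = build_cnn_lstm(cfg)
        model.lstm.Wx *= np.float32(wx_gain)
        model.head.W *= np.float32(head_gain)
        result = train(model, stack, labels, cfg, gdd=gdd,
                       stop_at_train_mae=target_train_mae, check_every=10,
                       collapse_check=collapse_check)
        if best is None or result.final_train_mae < best[1].final_train_mae:
            best = (model, result)
        if result.final_train_mae < target_train_mae:
            break
    return best


# -- data handling --------------------------------------------------------

AUGMENT_OPS = ("brightness", "contrast", "blur")


def augment_stack(stack: PlotImageSeries, fraction: float, seed: int = 0,
                  brightness_delta: float = 30.0, contrast_factor: float = 1.3,
                  blur_sigma: float = 1.0) -> tuple[PlotImageSeries, dict[int, str]]:
    """Perturb a random ``fraction`` of plots with one photometric change each.

    Each selected plot receives one of: a constant brightness shift, a
    contrast scaling about the mean, or a Gaussian blur, applied to all its
    flights; labels are untouched.  Returns the augmented stack and a
    {plot index: op} record.  Reproducible by ``seed``.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(stack.plot_ids)
    k = int(round(fraction * n))
    chosen = rng.choice(n, size=k, replace=False) if k else np.array([], dtype=int)
    data = stack.data.copy()
    applied: dict[int, str] = {}
    for p in sorted(chosen):
        op = AUGMENT_OPS[rng.integers(len(AUGMENT_OPS))]
        block = data[:, p].astype(float)
        if op == "brightness":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            block = block + sign * brightness_delta
        elif op == "contrast":
            mean = block.mean(axis=(1, 2), keepdims=True)
            block = (block - mean) * contrast_factor + mean
        else:
            block = np.stack([gaussian_filter(img, sigma=(blur_sigma, blur_sigma, 0))
                              for img in block])
        data[:, p] = np.clip(block, 0, 255).astype(stack.data.dtype)
        applied[int(p)] = op
    return PlotImageSeries(data, stack.flights, stack.plot_ids), applied


@dataclass
class SplitIndices:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def split_dataset(labels, test_fraction: float = 0.2, environment_ids=None,
                  seed: int = 0, val_fraction: float = 0.1) -> SplitIndices:
    """Environment-stratified train/val/test split of plot indices.

    ``test_fraction`` of each environment goes to test; ``val_fraction`` of
    the remaining training pool (again per environment) is held out for
    validation.  Partitions are disjoint and exhaustive, reproducible by seed.
    """
    n = len(labels)
    env = (np.zeros(n, dtype=int) if environment_ids is None
           else np.asarray(environment_ids))
    rng = np.random.default_rng(seed)
    train_idx, val_idx, test_idx = [], [], []
    for e in np.unique(env):
        members = np.flatnonzero(env == e)
        if members.size < 2:
            raise ValueError(f"environment {e!r} has fewer than 2 plots")
        members = rng.permutation(members)
        n_test = int(round(test_fraction * members.size))
        test_idx.append(members[:n_test])
        pool = members[n_test:]
        n_val = int(round(val_fraction * pool.size))
        val_idx.append(pool[:n_val])
        train_idx.append(pool[n_val:])
    return SplitIndices(train=np.sort(np.concatenate(train_idx)),
                        val=np.sort(np.concatenate(val_idx)),
                        test=np.sort(np.concatenate(test_idx)))
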
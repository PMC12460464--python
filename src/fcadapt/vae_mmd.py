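"""Semi-supervised VAE with MMD domain confusion for diagnostic transfer.

The model is a stacked deep generative classifier: a latent-feature
model (M1) encodes the FC vector x together with a domain one-hot d
into a Gaussian latent z1, and a generative semi-supervised model (M2)
encodes z1 and the class y into a second latent z2, with generative
paths p(x|z1,d) and p(z1|z2,y) and a classifier head q(y|z1).  Both
stages are trained jointly.  For labeled subjects the objective is the
(negated) evidence lower bound L_s plus an alpha-weighted
cross-entropy so the classifier also learns from labeled data; for
unlabeled subjects the bound L_T marginalizes L_s over the classes
under q(y|z1) minus the classifier entropy.  Domain confusion is
imposed by a beta-weighted squared maximum mean discrepancy (MMD)
between the z1 posterior means of every non-target domain and the
target domain, so the encoder is pushed to give all domains the same
latent distribution.  Everything is a single minimized loss

    (-ELBO terms) + alpha * CE + beta * sum_s MMD^2(z1_s, z1_target).

Auxiliary control-only cohorts enter as extra labeled source domains;
each contributes its own MMD pair to the target (transfer learning).

Gradients come from the package's tape-based autodiff engine; training
uses Adam.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ._autodiff import Adam, Tensor, concat, exp, log, relu

__all__ = [
    "VaeMmdConfig",
    "LossBreakdown",
    "VAEMMDClassifier",
    "mmd_squared",
    "median_heuristic_bandwidth",
    "total_loss",
    "train_vae_mmd",
    "save_checkpoint",
    "load_checkpoint",
]

_LOG2PI = float(np.log(2.0 * np.pi))
CLASS_ORDER = ("control", "autism", "asperger")
UNLABELED = "unknown"


@dataclass
class VaeMmdConfig:
    """Architecture and training settings.

    enc1_dim/enc2_dim are the first and second encoding-layer widths
    (2,000 and 1,000 by default, the published scale; tests use smaller).
    z1_dim/z2_dim default to a quarter of the corresponding encoder
    width.  alpha weights the classification term (larger = more purely
    discriminative), beta the MMD domain-confusion penalty (larger =
    stronger domain alignment).  batches_per_epoch fixes the number of
    minibatches per epoch for every domain (so cohorts of different
    sizes are trained simultaneously with equal batch counts);
    batch_size, if given, overrides the derived per-domain size.
    """

    input_dim: int = 19900
    enc1_dim: int = 2000
    enc2_dim: int = 1000
    z1_dim: int | None = None
    z2_dim: int | None = None
    n_classes: int = 3
    alpha: float = 500.0
    beta: float = 1.0
    kernel_bandwidth: float | str = "median"
    learning_rate: float = 1e-4
    epochs: int = 50
    batches_per_epoch: int = 20
    batch_size: int | None = None
    target_domain: str = "target"
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.z1_dim is None:
            self.z1_dim = max(2, self.enc1_dim // 4)
        if self.z2_dim is None:
            self.z2_dim = max(2, self.enc2_dim // 4)
        for name in ("input_dim", "enc1_dim", "enc2_dim", "z1_dim", "z2_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if isinstance(self.kernel_bandwidth, (int, float)) and self.kernel_bandwidth <= 0:
            raise ValueError("numeric kernel bandwidth must be positive")


@dataclass
class LossBreakdown:
    """Per-step (or per-epoch) components of the minimized objective."""

    labeled_elbo_sum: float = 0.0
    unlabeled_elbo_sum: float = 0.0
    classification_term: float = 0.0
    mmd_term: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.labeled_elbo_sum
            + self.unlabeled_elbo_sum
            + self.classification_term
            + self.mmd_term
        )

    def as_dict(self) -> dict:
        d = asdict(self)
        d["total"] = self.total
        return d


# ---------------------------------------------------------------------------
# parameters and forward passes
# ---------------------------------------------------------------------------


def init_params(config: VaeMmdConfig, n_domains: int,
                rng: np.random.Generator) -> dict[str, Tensor]:
    """He-scaled Gaussian initialization of all trainable tensors."""

    def dense(n_in, n_out):
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        return Tensor(w, requires_grad=True), Tensor(np.zeros(n_out), requires_grad=True)

    c = config
    p: dict[str, Tensor] = {}
    p["enc1_w"], p["enc1_b"] = dense(c.input_dim + n_domains, c.enc1_dim)
    p["enc1_mu_w"], p["enc1_mu_b"] = dense(c.enc1_dim, c.z1_dim)
    p["enc1_lv_w"], p["enc1_lv_b"] = dense(c.enc1_dim, c.z1_dim)
    p["cls_w"], p["cls_b"] = dense(c.z1_dim, c.n_classes)
    p["enc2_w"], p["enc2_b"] = dense(c.z1_dim + c.n_classes, c.enc2_dim)
    p["enc2_mu_w"], p["enc2_mu_b"] = dense(c.enc2_dim, c.z2_dim)
    p["enc2_lv_w"], p["enc2_lv_b"] = dense(c.enc2_dim, c.z2_dim)
    p["dec2_w"], p["dec2_b"] = dense(c.z2_dim + c.n_classes, c.enc2_dim)
    p["dec2_mu_w"], p["dec2_mu_b"] = dense(c.enc2_dim, c.z1_dim)
    p["dec1_w"], p["dec1_b"] = dense(c.z1_dim + n_domains, c.enc1_dim)
    p["dec1_mu_w"], p["dec1_mu_b"] = dense(c.enc1_dim, c.input_dim)
    p["logvar_z1"] = Tensor(np.zeros(c.z1_dim), requires_grad=True)
    p["logvar_x"] = Tensor(np.zeros(c.input_dim), requires_grad=True)
    return p


def encode_z1(params, x: np.ndarray, d: np.ndarray):
    """q(z1 | x, d): returns (mean, logvar) Tensors for a batch."""
    h = relu(concat([Tensor(x), Tensor(d)], axis=1) @ params["enc1_w"] + params["enc1_b"])
    mu = h @ params["enc1_mu_w"] + params["enc1_mu_b"]
    lv = h @ params["enc1_lv_w"] + params["enc1_lv_b"]
    return mu, lv


def classifier_log_probs(params, z1: Tensor) -> Tensor:
    """log q(y | z1), rows log-sum to 0 (softmax over classes)."""
    logits = z1 @ params["cls_w"] + params["cls_b"]
    m = Tensor(logits.data.max(axis=1, keepdims=True))  # detached shift
    lse = m + log(exp(logits - m).sum(axis=1, keepdims=True))
    return logits - lse


def encode_z2(params, z1: Tensor, y_onehot: np.ndarray):
    h = relu(concat([z1, Tensor(y_onehot)], axis=1) @ params["enc2_w"] + params["enc2_b"])
    mu = h @ params["enc2_mu_w"] + params["enc2_mu_b"]
    lv = h @ params["enc2_lv_w"] + params["enc2_lv_b"]
    return mu, lv


def decode_z1_mean(params, z2: Tensor, y_onehot: np.ndarray) -> Tensor:
    h = relu(concat([z2, Tensor(y_onehot)], axis=1) @ params["dec2_w"] + params["dec2_b"])
    return h @ params["dec2_mu_w"] + params["dec2_mu_b"]


def decode_x_mean(params, z1: Tensor, d: np.ndarray) -> Tensor:
    h = relu(concat([z1, Tensor(d)], axis=1) @ params["dec1_w"] + params["dec1_b"])
    return h @ params["dec1_mu_w"] + params["dec1_mu_b"]


def _gauss_logpdf(x, mu, logvar) -> Tensor:
    """Diagonal-Gaussian log density, summed over dimensions (per row)."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    diff = x - mu
    return (-0.5 * (Tensor(_LOG2PI) + logvar + diff * diff * exp(-logvar))).sum(axis=1)


def negelbo_given_z1(params, x, d, z1, mu1, lv1, y_onehot, eps2, n_classes=3):
    """Per-sample negative ELBO L_s for known class, given the z1 sample.

    Single-sample reparameterized estimate of
    -log p(x|z1,d) - log p(z1|z2,y) - log p(z2) - log p(y)
    + log q(z1|x,d) + log q(z2|z1,y).
    """
    mu2, lv2 = encode_z2(params, z1, y_onehot)
    z2 = mu2 + exp(0.5 * lv2) * Tensor(eps2)
    recon = _gauss_logpdf(x, decode_x_mean(params, z1, d), params["logvar_x"])
    prior_z1 = _gauss_logpdf(z1, decode_z1_mean(params, z2, y_onehot), params["logvar_z1"])
    prior_z2 = _gauss_logpdf(z2, Tensor(np.zeros_like(eps2)), Tensor(np.zeros_like(eps2)))
    logq_z1 = _gauss_logpdf(z1, mu1, lv1)
    logq_z2 = _gauss_logpdf(z2, mu2, lv2)
    log_py = float(np.log(n_classes))  # -log p(y) under uniform prior
    return -recon - prior_z1 - prior_z2 + log_py + logq_z1 + logq_z2


def loss_labeled(params, x, d, y_idx, config: VaeMmdConfig, eps):
    """Labeled contribution: (sum of L_s, alpha * cross-entropy).

    eps is a dict with recorded standard-normal draws {"z1", "z2"}.
    Returns (elbo_sum Tensor, classification Tensor, z1_mean Tensor).
    """
    nc = config.n_classes
    y_onehot = np.eye(nc)[np.asarray(y_idx)]
    mu1, lv1 = encode_z1(params, x, d)
    z1 = mu1 + exp(0.5 * lv1) * Tensor(eps["z1"])
    ls = negelbo_given_z1(params, x, d, z1, mu1, lv1, y_onehot, eps["z2"], nc)
    elbo_sum = ls.sum()
    if config.alpha == 0:
        return elbo_sum, Tensor(0.0), mu1
    logp = classifier_log_probs(params, z1)
    ce = -(logp * Tensor(y_onehot)).sum()
    return elbo_sum, config.alpha * ce, mu1


def loss_unlabeled(params, x, d, config: VaeMmdConfig, eps):
    """Unlabeled contribution: sum over batch of

    L_T = sum_y q(y|z1) L_s(x, d, y) - H(q(y|z1)),

    the exact marginalization over the class variable.  eps holds draws
    {"z1": (B, z1_dim), "z2": (n_classes, B, z2_dim)}.
    Returns (L_T sum Tensor, z1_mean Tensor).
    """
    nc = config.n_classes
    mu1, lv1 = encode_z1(params, x, d)
    z1 = mu1 + exp(0.5 * lv1) * Tensor(eps["z1"])
    logp = classifier_log_probs(params, z1)
    q = exp(logp)
    total = (q * logp).sum()  # -H(q), summed over batch
    for c in range(nc):
        y_onehot = np.zeros((x.shape[0], nc))
        y_onehot[:, c] = 1.0
        ls_c = negelbo_given_z1(params, x, d, z1, mu1, lv1, y_onehot, eps["z2"][c], nc)
        total = total + (q[:, c] * ls_c).sum()
    return total, mu1


# ---------------------------------------------------------------------------
# maximum mean discrepancy
# ---------------------------------------------------------------------------


def median_heuristic_bandwidth(a: np.ndarray, b: np.ndarray) -> float:
    """RBF bandwidth sigma with 2*sigma^2 = median pairwise squared distance
    of the pooled samples (off-diagonal pairs)."""
    pooled = np.vstack([np.atleast_2d(a), np.atleast_2d(b)])
    sq = ((pooled[:, None, :] - pooled[None, :, :]) ** 2).sum(-1)
    off = sq[~np.eye(len(pooled), dtype=bool)]
    med = np.median(off) if off.size else 0.0
    return float(np.sqrt(med / 2.0)) if med > 0 else 1.0


def _pairwise_sq_dists(a: Tensor, b: Tensor) -> Tensor:
    ra = (a * a).sum(axis=1, keepdims=True)
    rb = (b * b).sum(axis=1, keepdims=True)
    return ra + rb.T - 2.0 * (a @ b.T)


def mmd_squared(a, b, bandwidth: float | str = "median"):
    """Biased (V-statistic) squared MMD with an RBF kernel.

    mean k(a,a') + mean k(b,b') - 2 mean k(a,b), with
    k(u,v) = exp(-||u-v||^2 / (2 sigma^2)).  Symmetric in (a, b) and
    non-negative.  Accepts Tensors (differentiable) or arrays; 1-D
    inputs are treated as single-dimension sample sets.
    """
    ta = a if isinstance(a, Tensor) else Tensor(np.atleast_2d(np.asarray(a, dtype=float)).reshape(len(np.atleast_1d(a)), -1))
    tb = b if isinstance(b, Tensor) else Tensor(np.atleast_2d(np.asarray(b, dtype=float)).reshape(len(np.atleast_1d(b)), -1))
    if ta.data.size == 0 or tb.data.size == 0:
        raise ValueError("mmd_squared requires non-empty sample sets")
    if bandwidth == "median":
        sigma = median_heuristic_bandwidth(ta.data, tb.data)
    else:
        sigma = float(bandwidth)
    gamma = 1.0 / (2.0 * sigma**2)
    kaa = exp(_pairwise_sq_dists(ta, ta) * (-gamma)).mean()
    kbb = exp(_pairwise_sq_dists(tb, tb) * (-gamma)).mean()
    kab = exp(_pairwise_sq_dists(ta, tb) * (-gamma)).mean()
    out = kaa + kbb - 2.0 * kab
    return out if (ta.requires_grad or tb.requires_grad) else float(max(out.data, 0.0))


def total_loss(params, batches: dict, config: VaeMmdConfig,
               rng: np.random.Generator):
    """One optimization step's full objective over per-domain batches.

    ``batches`` maps domain id -> dict with keys ``x`` (B, input_dim),
    ``d`` (B, n_domains one-hot), ``y_idx`` (B,) class indices, and
    ``labeled`` (B,) boolean mask.  Labeled rows contribute L_s plus
    the alpha-weighted cross-entropy; unlabeled rows contribute the
    marginalized L_T.  With beta > 0 every non-target domain adds one
    beta-weighted MMD pair against the target's z1 posterior means;
    with beta = 0 the MMD graph is never constructed.

    Returns (loss Tensor, LossBreakdown, number of MMD pairs).
    """
    loss = Tensor(0.0)
    bd = LossBreakdown()
    z1_means: dict = {}
    for v in sorted(batches):
        b = batches[v]
        x, d = np.asarray(b["x"]), np.asarray(b["d"])
        labeled = np.asarray(b["labeled"], dtype=bool)
        y_idx = np.asarray(b.get("y_idx", np.zeros(len(x), dtype=int)))
        mus = []
        if labeled.any():
            lab = np.flatnonzero(labeled)
            eps = {
                "z1": rng.standard_normal((lab.size, config.z1_dim)),
                "z2": rng.standard_normal((lab.size, config.z2_dim)),
            }
            elbo, ce, mu1 = loss_labeled(
                params, x[lab], d[lab], y_idx[lab], config, eps
            )
            loss = loss + elbo + ce
            bd.labeled_elbo_sum += float(elbo.data)
            bd.classification_term += float(ce.data)
            mus.append(mu1)
        if (~labeled).any():
            unl = np.flatnonzero(~labeled)
            eps = {
                "z1": rng.standard_normal((unl.size, config.z1_dim)),
                "z2": rng.standard_normal(
                    (config.n_classes, unl.size, config.z2_dim)
                ),
            }
            lt, mu1 = loss_unlabeled(params, x[unl], d[unl], config, eps)
            loss = loss + lt
            bd.unlabeled_elbo_sum += float(lt.data)
            mus.append(mu1)
        if mus:
            z1_means[v] = mus[0] if len(mus) == 1 else concat(mus, axis=0)
    n_pairs = 0
    use_mmd = (
        config.beta > 0
        and config.target_domain in z1_means
        and len(z1_means) > 1
    )
    if use_mmd:
        tgt = z1_means[config.target_domain]
        for v in sorted(z1_means):
            if v == config.target_domain:
                continue
            pair = mmd_squared(z1_means[v], tgt, config.kernel_bandwidth)
            loss = loss + config.beta * pair
            bd.mmd_term += config.beta * float(pair.data)
            n_pairs += 1
    return loss, bd, n_pairs


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class VAEMMDClassifier(ClassifierMixin, BaseEstimator):
    """Semi-supervised VAE-MMD domain-adaptation classifier.

    fit(X, y, domain=...) takes the feature matrix, a label array in
    which unlabeled subjects carry the token "unknown", and a parallel
    array of domain identifiers.  Rows of every domain other than
    ``target_domain`` pull an MMD penalty toward the target's latent
    distribution.  predict encodes with the posterior mean (no
    sampling) and takes the arg-max class; exact ties resolve to the
    lowest class index.

    Fitted attributes: ``params_`` (tensor dict), ``classes_``,
    ``domains_``, ``history_`` (per-epoch loss breakdown and training
    accuracy), ``w1_checkpoints_`` (per-epoch copies of the first
    encoding layer's input weights, for feature importance).
    """

    def __init__(self, input_dim=None, enc1_dim=2000, enc2_dim=1000,
                 z1_dim=None, z2_dim=None, n_classes=3, alpha=500.0, beta=1.0,
                 kernel_bandwidth="median", learning_rate=1e-4, epochs=50,
                 batches_per_epoch=20, batch_size=None,
                 target_domain="target", seed=0):
        self.input_dim = input_dim
        self.enc1_dim = enc1_dim
        self.enc2_dim = enc2_dim
        self.z1_dim = z1_dim
        self.z2_dim = z2_dim
        self.n_classes = n_classes
        self.alpha = alpha
        self.beta = beta
        self.kernel_bandwidth = kernel_bandwidth
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batches_per_epoch = batches_per_epoch
        self.batch_size = batch_size
        self.target_domain = target_domain
        self.seed = seed

    # -- config plumbing -------------------------------------------------
    def _config(self, n_features: int) -> VaeMmdConfig:
        return VaeMmdConfig(
            input_dim=self.input_dim or n_features,
            enc1_dim=self.enc1_dim, enc2_dim=self.enc2_dim,
            z1_dim=self.z1_dim, z2_dim=self.z2_dim,
            n_classes=self.n_classes, alpha=self.alpha, beta=self.beta,
            kernel_bandwidth=self.kernel_bandwidth,
            learning_rate=self.learning_rate, epochs=self.epochs,
            batches_per_epoch=self.batches_per_epoch,
            batch_size=self.batch_size, target_domain=self.target_domain,
            seed=self.seed,
        )

    def _class_index(self, labels: np.ndarray) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.classes_)}
        return np.array([lut[v] for v in labels])

    # -- training --------------------------------------------------------
    def fit(self, X, y, domain=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or len(y) != len(X):
            raise ValueError("X must be 2-D with one label per row")
        if domain is None:
            domain = np.array(["source"] * len(X))
        domain = np.asarray(domain, dtype=object)
        config = self._config(X.shape[1])
        if X.shape[1] != config.input_dim:
            raise ValueError("input_dim does not match X")

        observed = [v for v in y if v != UNLABELED]
        if not observed:
            raise ValueError("no labeled rows; semi-supervision needs labeled data")
        uniq = set(observed)
        if uniq <= set(CLASS_ORDER):
            # canonical diagnosis ordering: control < autism < asperger
            self.classes_ = np.array(CLASS_ORDER, dtype=object)
        else:
            self.classes_ = np.array(sorted(uniq), dtype=object)
        config.n_classes = len(self.classes_)

        self.domains_ = sorted(set(domain.tolist()))
        dom_lut = {v: i for i, v in enumerate(self.domains_)}
        d_onehot = np.eye(len(self.domains_))[[dom_lut[v] for v in domain]]
        has_target = config.target_domain in dom_lut
        if config.beta > 0 and len(self.domains_) > 1 and not has_target:
            raise ValueError(
                f"beta > 0 but target domain {config.target_domain!r} absent"
            )

        rng = np.random.default_rng(config.seed)
        params = init_params(config, len(self.domains_), rng)
        opt = Adam(list(params.values()), lr=config.learning_rate)

        labeled_mask = y != UNLABELED
        y_idx = np.zeros(len(y), dtype=int)
        y_idx[labeled_mask] = self._class_index(y[labeled_mask])

        dom_rows = {v: np.flatnonzero(domain == v) for v in self.domains_}

        self.history_ = []
        self.w1_checkpoints_ = []
        for epoch in range(config.epochs):
            chunks = {}
            for v, rows in dom_rows.items():
                perm = rng.permutation(rows)
                if config.batch_size:
                    nb = max(1, int(np.ceil(len(rows) / config.batch_size)))
                    nb = min(nb, config.batches_per_epoch)
                else:
                    nb = config.batches_per_epoch
                chunks[v] = [c for c in np.array_split(perm, nb)]
            epoch_bd = LossBreakdown()
            n_steps = max(len(c) for c in chunks.values())
            for step in range(n_steps):
                batches = {}
                for v in self.domains_:
                    rows = chunks[v][step % len(chunks[v])]
                    if rows.size == 0:
                        continue
                    batches[v] = {
                        "x": X[rows],
                        "d": d_onehot[rows],
                        "y_idx": y_idx[rows],
                        "labeled": labeled_mask[rows],
                    }
                loss, bd, _ = total_loss(params, batches, config, rng)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, step {step}: "
                        f"{bd.as_dict()}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                for f in ("labeled_elbo_sum", "unlabeled_elbo_sum",
                          "classification_term", "mmd_term"):
                    setattr(epoch_bd, f, getattr(epoch_bd, f) + getattr(bd, f))
            self.params_ = params
            self.config_ = config
            self._dom_lut_ = dom_lut
            acc = float(
                np.mean(
                    self.predict(X[labeled_mask], domain=domain[labeled_mask])
                    == y[labeled_mask]
                )
            )
            rec = epoch_bd.as_dict()
            rec.update(epoch=epoch, train_accuracy=acc)
            self.history_.append(rec)
            self.w1_checkpoints_.append(params["enc1_w"].data.copy())
        return self

    # -- inference -------------------------------------------------------
    def _domain_onehot(self, n, domain):
        if domain is None:
            d = np.zeros((n, len(self.domains_)))
            d[:, 0] = 1.0
            return d
        domain = np.asarray(domain, dtype=object)
        unknown = set(domain.tolist()) - set(self.domains_)
        if unknown:
            raise ValueError(f"unseen domain id(s) {sorted(unknown)}")
        return np.eye(len(self.domains_))[[self._dom_lut_[v] for v in domain]]

    def predict_proba(self, X, domain=None):
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=np.float64)
        d = self._domain_onehot(len(X), domain)
        mu1, _ = encode_z1(self.params_, X, d)
        logp = classifier_log_probs(self.params_, mu1)
        if not np.all(np.isfinite(logp.data)):
            raise RuntimeError("non-finite classifier output; model diverged?")
        return np.exp(logp.data)

    def predict(self, X, domain=None):
        proba = self.predict_proba(X, domain=domain)
        return self.classes_[np.argmax(proba, axis=1)]

    def encode(self, X, domain=None) -> np.ndarray:
        """Posterior mean of z1 for each row (the domain-invariant latent)."""
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=np.float64)
        mu1, _ = encode_z1(self.params_, X, self._domain_onehot(len(X), domain))
        return mu1.data


def train_vae_mmd(X, y, domain, **config_kwargs) -> VAEMMDClassifier:
    """Functional wrapper: construct and fit a :class:`VAEMMDClassifier`."""
    return VAEMMDClassifier(**config_kwargs).fit(X, y, domain=domain)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(clf: VAEMMDClassifier, path) -> None:
    """Archive the fitted model: config JSON + parameter tensors (npz)."""
    check_is_fitted(clf, "params_")
    path = Path(path)
    meta = {
        "format_version": 1,
        "config": asdict(clf.config_),
        "classes": clf.classes_.tolist(),
        "domains": clf.domains_,
    }
    arrays = {k: v.data for k, v in clf.params_.items()}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> VAEMMDClassifier:
    with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = meta["config"]
    clf = VAEMMDClassifier(
        input_dim=cfg["input_dim"], enc1_dim=cfg["enc1_dim"],
        enc2_dim=cfg["enc2_dim"], z1_dim=cfg["z1_dim"], z2_dim=cfg["z2_dim"],
        n_classes=cfg["n_classes"], alpha=cfg["alpha"], beta=cfg["beta"],
        kernel_bandwidth=cfg["kernel_bandwidth"],
        learning_rate=cfg["learning_rate"], epochs=cfg["epochs"],
        batches_per_epoch=cfg["batches_per_epoch"],
        batch_size=cfg["batch_size"], target_domain=cfg["target_domain"],
        seed=cfg["seed"],
    )
    clf.config_ = VaeMmdConfig(**cfg)
    clf.classes_ = np.array(meta["classes"], dtype=object)
    clf.domains_ = list(meta["domains"])
    clf._dom_lut_ = {v: i for i, v in enumerate(clf.domains_)}
    clf.params_ = {k: Tensor(v, requires_grad=True) for k, v in arrays.items()}
    clf.history_ = []
    clf.w1_checkpoints_ = [clf.params_["enc1_w"].data.copy()]
    return clf
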
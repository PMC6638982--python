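"""Model/Results interface over the fitting machinery.

``ObserverModel`` binds one subject's session (trials plus responses) to one
observer model and task; ``fit`` evaluates the posterior over parameters on
a grid (MAP + log marginal likelihood) or, for high-dimensional models, by
bounded multi-start maximum likelihood.  The returned ``ObserverResults``
carries the estimates, evidence and information criteria, prints a summary
table, and exposes posterior-predictive simulation.

Example
-------
>>> from probtrack import TaskConfig, simulate_session, ObserverModel
>>> trials, resp = simulate_session(TaskConfig(seed=1), "exp_bias",
...                                 {"alpha": 0.17, "w": 0.58}, "covert")
>>> res = ObserverModel(trials, resp, model="exp_bias").fit(n_grid=30)
>>> round(res.params["alpha"], 2)  # doctest: +SKIP
0.17
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitting import (
    FitResult,
    grid_log_posterior,
    marginal_likelihood,
    param_priors,
    point_estimates,
    sequence_log_likelihood,
)
from .io import frame_to_session
from .observers import MODEL_IDS
from .recovery import posterior_predictive
from .task import ResponseRecord, TaskConfig, TrialSequence, simulate_session

__all__ = ["ObserverModel", "ObserverResults"]


class ObserverModel:
    """One observer model bound to one subject's session.

    Parameters
    ----------
    trials, responses
        The session data (see :mod:`probtrack.task`).
    model
        Observer model id (one of ``probtrack.MODEL_IDS``).
    task
        ``"covert"`` or ``"overt"``; defaults to the response record's task.
    config
        Generative/task configuration; defaults to the one attached to the
        trial sequence.
    """

    def __init__(self, trials: TrialSequence, responses: ResponseRecord,
                 model: str = "exp_bias", task: str | None = None,
                 config: TaskConfig | None = None,
                 subject: str | None = None):
        if model not in MODEL_IDS:
            raise KeyError(f"unknown model {model!r}; choose from "
                           f"{MODEL_IDS}")
        self.trials = trials
        self.responses = responses
        self.model = model
        self.task = task or responses.task
        self.config = config or trials.config or TaskConfig(
            n_trials=len(trials))
        self.subject = subject
        self.priors = param_priors(model, self.task)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model: str = "exp_bias",
                       task: str | None = None,
                       config: TaskConfig | None = None,
                       subject: str | None = None) -> "ObserverModel":
        trials, responses = frame_to_session(df, task=task, config=config)
        return cls(trials, responses, model=model, config=config,
                   subject=subject)

    @classmethod
    def simulate(cls, model: str, params: dict, task: str = "covert",
                 config: TaskConfig | None = None,
                 seed: int | None = None) -> "ObserverModel":
        """Simulate a synthetic subject and bind it to its own model."""
        config = config or TaskConfig()
        trials, responses = simulate_session(config, model, params, task,
                                             rng_seed=seed)
        return cls(trials, responses, model=model, config=config)

    def loglike(self, params: dict, **kwargs) -> float:
        """Log likelihood of the session at a natural-scale parameter dict."""
        return sequence_log_likelihood(self.trials, self.responses,
                                       self.model, params, self.task,
                                       self.config, **kwargs)

    def fit(self, method: str = "grid", n_grid: int | None = None,
            n_restarts: int = 20, seed: int = 0) -> "ObserverResults":
        """Fit the model and return an :class:`ObserverResults`.

        ``method="grid"`` (default) evaluates the full posterior grid and
        integrates it for the log marginal likelihood; models with more than
        four parameters automatically fall back to ``method="mle"``.
        """
        if method == "grid" and len(self.priors) > 4:
            method = "mle"
        if method == "grid":
            grid = grid_log_posterior(self.trials, self.responses,
                                      self.model, self.task, self.config,
                                      n_grid=n_grid, mc_seed=seed)
            lml = marginal_likelihood(grid)
            map_params = grid.map_estimate()
            max_ll = float(grid.log_like.max())
            k, n = len(self.priors), len(self.trials)
            fr = FitResult(self.model, self.task, n, lml=lml,
                           map_params=map_params, max_loglik=max_ll,
                           aic=2 * k - 2 * max_ll,
                           bic=k * np.log(n) - 2 * max_ll,
                           subject=self.subject, grid=grid)
        elif method == "mle":
            fr = point_estimates(self.trials, self.responses, self.model,
                                 self.task, self.config,
                                 n_restarts=n_restarts, seed=seed)
            fr.subject = self.subject
        else:
            raise ValueError("method must be 'grid' or 'mle'")
        return ObserverResults(self, fr)


class ObserverResults:
    """Estimates, evidence and diagnostics from an :class:`ObserverModel` fit."""

    def __init__(self, model: ObserverModel, fitresult: FitResult):
        self.model = model
        self.fitresult = fitresult

    @property
    def params(self) -> dict:
        return self.fitresult.map_params or self.fitresult.mle_params

    @property
    def lml(self) -> float | None:
        return self.fitresult.lml

    @property
    def aic(self) -> float | None:
        return self.fitresult.aic

    @property
    def bic(self) -> float | None:
        return self.fitresult.bic

    @property
    def grid(self):
        return self.fitresult.grid

    def posterior_predictive(self, **kwargs):
        if self.grid is None:
            raise ValueError("posterior predictive requires a grid fit")
        return posterior_predictive(self.grid, self.model.trials,
                                    self.model.model,
                                    config=self.model.config,
                                    responses=self.model.responses,
                                    **kwargs)

    def summary(self) -> str:
        fr = self.fitresult
        lines = [
            "Observer model fit",
            "=" * 46,
            f"Model:        {fr.model:>12}   Task:   {fr.task:>8}",
            f"N trials:     {fr.n_trials:>12d}   Method: "
            f"{'grid' if fr.grid is not None else 'mle':>8}",
        ]
        if fr.lml is not None:
            lines.append(f"log marginal likelihood: {fr.lml:12.3f}")
        if fr.max_loglik is not None:
            lines.append(f"max log likelihood:      {fr.max_loglik:12.3f}")
        if fr.aic is not None:
            lines.append(f"AIC: {fr.aic:10.2f}    BIC: {fr.bic:10.2f}")
        lines.append("-" * 46)
        est = self.params or {}
        kind = "MAP" if fr.map_params else "MLE"
        lines.append(f"{'parameter':<14}{kind:>12}")
        for name, val in est.items():
            lines.append(f"{name:<14}{val:>12.4f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<ObserverResults {self.fitresult.model}/{self.fitresult.task}"
                f" lml={self.fitresult.lml}>")
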
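"""Stage-1 execution: query every registered model client for a case set.

The orchestrator enforces the execution contract, not any vendor API: each
(model, case) pair gets exactly one recorded status, failures become
status-only responses rather than exceptions, and results are independent
of execution order.  Live API clients are deliberately outside the tested
surface; the repo ships the client contract, a scriptable mock client, and
the synthetic simulator (a drop-in Stage 1), so the full pipeline runs
offline.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Iterable, Mapping, Optional, Protocol, Sequence, runtime_checkable

from pydantic import BaseModel, ConfigDict

from medley.errors import ValidationError
from medley.ingest import ClinicalCase, ModelResponse, write_responses
from medley.registry import Registry

log = logging.getLogger(__name__)


@runtime_checkable
class ModelClient(Protocol):
    """Contract for one queryable diagnostic model."""

    model_id: str

    def query(self, case: ClinicalCase, budget_s: float) -> ModelResponse:
        """Return a response for the case; failures are statuses, not raises."""
        ...


class MockClient:
    """Scriptable client for tests: fixed responses and/or failure statuses.

    ``script`` maps case_id -> either a ready ModelResponse or a failure
    status string ("timeout", "overflow", "error").  Unscripted cases get
    an ok response with no candidates.
    """

    def __init__(self, model_id: str, script: Mapping[str, ModelResponse | str] | None = None):
        self.model_id = model_id
        self.script = dict(script or {})

    def query(self, case: ClinicalCase, budget_s: float) -> ModelResponse:
        entry = self.script.get(case.case_id)
        if entry is None:
            return ModelResponse(model_id=self.model_id, case_id=case.case_id, status="ok", candidates=())
        if isinstance(entry, str):
            return ModelResponse(model_id=self.model_id, case_id=case.case_id, status=entry)  # type: ignore[arg-type]
        return entry


class RunRecord(BaseModel):
    """Audit trail for one ensemble run."""

    model_config = ConfigDict(frozen=True)

    run_id: str
    case_ids: tuple[str, ...]
    model_ids: tuple[str, ...]
    statuses: dict[str, str]  # "model_id/case_id" -> status
    seed: Optional[int] = None
    config_snapshot: dict = {}
    elapsed_s: Optional[float] = None  # informational only


def run_ensemble(
    clients: Sequence[ModelClient],
    cases: Sequence[ClinicalCase],
    registry: Registry,
    *,
    budget_s: float = 30.0,
    run_id: str = "run",
    seed: int | None = None,
    config_snapshot: dict | None = None,
    out_path: str | Path | None = None,
) -> tuple[list[ModelResponse], RunRecord]:
    """Query every client for every case; exactly-once status accounting.

    Clients whose query raises are recorded with status ``error``; a client
    overrunning its time budget is recorded as ``timeout`` (post-hoc — the
    contract is bookkeeping, not preemption).  Output ordering is canonical
    (case, then model), so shuffling the client list changes nothing
    downstream.  When ``out_path`` is given the responses are also written
    as JSONL.
    """
    if not clients:
        raise ValidationError("run_ensemble requires at least one client")
    if not cases:
        raise ValidationError("run_ensemble requires at least one case")
    missing = [c.model_id for c in clients if c.model_id not in registry]
    if missing:
        raise ValidationError(f"client ids missing from registry: {missing}")
    ids = [c.model_id for c in clients]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate client model_ids")

    t0 = time.monotonic()
    responses: dict[tuple[str, str], ModelResponse] = {}
    statuses: dict[str, str] = {}
    for client in clients:
        for case in cases:
            t_query = time.monotonic()
            try:
                resp = client.query(case, budget_s)
                if resp.model_id != client.model_id:
                    raise ValidationError(
                        f"client {client.model_id!r} returned response for {resp.model_id!r}"
                    )
                if time.monotonic() - t_query > budget_s:
                    resp = ModelResponse(
                        model_id=client.model_id, case_id=case.case_id, status="timeout"
                    )
            except ValidationError:
                raise
            except Exception as exc:
                log.warning("client %s failed on case %s: %s", client.model_id, case.case_id, exc)
                resp = ModelResponse(model_id=client.model_id, case_id=case.case_id, status="error")
            responses[(case.case_id, client.model_id)] = resp
            statuses[f"{client.model_id}/{case.case_id}"] = resp.status
            log.debug("query model=%s case=%s status=%s", client.model_id, case.case_id, resp.status)

    # canonical ordering: by case then model, independent of client order
    ordered = [responses[key] for key in sorted(responses)]
    record = RunRecord(
        run_id=run_id,
        case_ids=tuple(c.case_id for c in cases),
        model_ids=tuple(sorted(ids)),
        statuses=statuses,
        seed=seed,
        config_snapshot=config_snapshot or {},
        elapsed_s=time.monotonic() - t0,
    )
    if out_path is not None:
        write_responses(ordered, out_path)
    return ordered, record


def split_by_case(responses: Iterable[ModelResponse]) -> dict[str, list[ModelResponse]]:
    """Group a response stream by case_id (insertion order preserved)."""
    out: dict[str, list[ModelResponse]] = {}
    for r in responses:
        out.setdefault(r.case_id, []).append(r)
    return out
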
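"""Teaching-exercise builder and grader.

An exercise set is a folder hierarchy: any folder containing one or more
JCAMP-DX spectra and exactly one molfile (the hidden solution) is a leaf
exercise; intermediate folders become categories.  :func:`build_toc` walks the
tree deterministically, emits ``toc.json`` plus a per-exercise
``exercise.json`` (with the molecular formula shown to students, computed
from the solution), and returns the in-memory :class:`ExerciseSet`.

Grading never reveals the solution structure: the verdict carries only the
comparison outcome and a formula-match note.  Student project bundles redact
the solution molecule entirely; instructor bundles include it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .molecule import Molecule, check_answer, molecular_formula, parse_molfile
from .project import Project, import_any, save_project

__all__ = [
    "Exercise",
    "ExerciseSet",
    "GradeResult",
    "ExerciseError",
    "build_toc",
    "grade_exercise",
    "export_student_bundle",
]


class ExerciseError(ValueError):
    pass


@dataclass
class Exercise:
    id: str
    spectra: list[Path]
    solution: Molecule
    shown_formula: str
    difficulty: str | None = None


@dataclass
class ExerciseSet:
    toc: dict
    exercises: list[Exercise] = field(default_factory=list)

    def exercise(self, exercise_id: str) -> Exercise:
        for ex in self.exercises:
            if ex.id == exercise_id:
                return ex
        raise KeyError(exercise_id)


@dataclass
class GradeResult:
    verdict: str  # correct | wrong_constitution | wrong_stereo
    formula_match: bool

    @property
    def correct(self) -> bool:
        return self.verdict == "correct"


_SPECTRUM_SUFFIXES = (".jdx", ".dx")


def build_toc(root: str | Path, write_files: bool = True) -> ExerciseSet:
    """Walk an exercise folder tree into an :class:`ExerciseSet`.

    Deterministic (lexicographic order) and idempotent; re-running writes
    byte-identical ``toc.json``/``exercise.json`` files.  A leaf folder with
    zero or more than one molfile raises :class:`ExerciseError` naming it.
    """
    root = Path(root)
    if not root.is_dir():
        raise ExerciseError(f"exercise root {root} does not exist")
    exercises: list[Exercise] = []
    toc = _walk(root, root, exercises)
    if toc is None:
        raise ExerciseError(f"exercise root {root} contains no exercises")
    out = ExerciseSet(toc=toc, exercises=exercises)
    if write_files:
        (root / "toc.json").write_text(
            json.dumps(toc, sort_keys=True, indent=1) + "\n", encoding="utf-8"
        )
        for ex in exercises:
            folder = root / ex.id
            doc = {
                "id": ex.id,
                "formula": ex.shown_formula,
                "spectra": [p.name for p in ex.spectra],
                "difficulty": ex.difficulty,
            }
            (folder / "exercise.json").write_text(
                json.dumps(doc, sort_keys=True, indent=1) + "\n", encoding="utf-8"
            )
    return out


def _walk(folder: Path, root: Path, exercises: list[Exercise]) -> dict | None:
    spectra = sorted(p for p in folder.iterdir()
                     if p.is_file() and p.suffix.lower() in _SPECTRUM_SUFFIXES)
    molfiles = sorted(p for p in folder.iterdir()
                      if p.is_file() and p.suffix.lower() == ".mol")
    subdirs = sorted(p for p in folder.iterdir() if p.is_dir())
    if spectra:
        if len(molfiles) != 1:
            raise ExerciseError(
                f"exercise folder {folder} has {len(molfiles)} molfiles; exactly one required"
            )
        solution = parse_molfile(molfiles[0].read_text())
        rel = folder.relative_to(root).as_posix()
        ex = Exercise(
            id=rel if rel != "." else folder.name,
            spectra=spectra,
            solution=solution,
            shown_formula=molecular_formula(solution),
            difficulty=_read_difficulty(folder),
        )
        exercises.append(ex)
        return {"type": "exercise", "id": ex.id, "formula": ex.shown_formula,
                "n_spectra": len(spectra),
                **({"difficulty": ex.difficulty} if ex.difficulty else {})}
    children = {}
    for sub in subdirs:
        node = _walk(sub, root, exercises)
        if node is not None:
            children[sub.name] = node
    if not children:
        return None
    return {"type": "category", "children": children}


def _read_difficulty(folder: Path) -> str | None:
    meta = folder / "meta.json"
    if meta.exists():
        try:
            return json.loads(meta.read_text()).get("difficulty")
        except (json.JSONDecodeError, AttributeError):
            return None
    return None


def grade_exercise(ex: Exercise, candidate: Molecule, stereo: bool = False) -> GradeResult:
    """Compare a student's structure against the hidden solution."""
    verdict = check_answer(candidate, ex.solution, stereo=stereo)
    return GradeResult(
        verdict=verdict,
        formula_match=molecular_formula(candidate) == ex.shown_formula,
    )


def export_student_bundle(ex: Exercise, out: str | Path,
                          include_solution: bool = False) -> None:
    """Write a project bundle for an exercise.

    The student variant contains the spectra and the shown formula but not
    the solution structure; ``include_solution=True`` produces the instructor
    variant.
    """
    project = Project()
    for path in ex.spectra:
        imported = import_any(path)
        for entry in imported.spectra:
            entry.id = f"{ex.id}/{path.name}" if len(ex.spectra) > 1 else ex.id
            project.spectra.append(entry)
    project.display = {"exercise_id": ex.id, "formula": ex.shown_formula}
    if include_solution:
        project.molecules.append((f"{ex.id}/solution", ex.solution))
    save_project(project, out)
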
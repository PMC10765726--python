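"""Offline test assets: the shipped recipe catalog, toy data trees, and a
mock bucket.

The catalog holds the fifteen pre-built curation recipes the package ships
(GENCODE/Ensembl/UCSC downloads, GATK bundle fetches, aligner index
builders, and the parameterless ``echo_out`` demonstration recipe). The
network-dependent recipes carry their upstream origin URLs and are meant
for schema validation and CWL rendering offline — only ``echo_out`` (and
any recipe whose ``origin`` is empty) is executable without a network.

Toy data trees and the mock bucket are generated deterministically from a
seed so every other module can be exercised end to end with zero downloads.
"""

from __future__ import annotations

import random
from pathlib import Path

from .evaluator import compute_md5, evaluate
from .exporter import MANIFEST_COLUMNS, MANIFEST_NAME, canonical_params
from .recipe import (
    OutputSpec,
    ParameterSpec,
    Recipe,
    SoftwareRequirement,
    write_recipe,
)

__all__ = [
    "CATALOG_NAMES",
    "OFFLINE_RECIPES",
    "catalog_recipes",
    "echo_out_recipe",
    "make_catalog",
    "make_toy_data_tree",
    "make_mock_bucket",
]


def _p(name, ptype="string", required=True, default=None, description=""):
    return ParameterSpec(name, ptype, required, default, description)


def _o(name, glob, role="primary"):
    return OutputSpec(name, glob, role)


def _conda(tool, spec, version="unversioned"):
    return SoftwareRequirement(tool, version, "conda-spec", spec)


def _sys(tool):
    return SoftwareRequirement(tool, "unversioned", "system", "")


def echo_out_recipe() -> Recipe:
    """The offline demonstration recipe: print a string into a txt file."""
    return Recipe(
        name="echo_out",
        version="1.0.0",
        description="Print a character string and output as a txt file",
        script_template='echo "{{input}}" > {{outfile}}.txt\n',
        parameters=(
            _p("input", description="Character string to print"),
            _p("outfile", description="Output file basename (without .txt)"),
        ),
        outputs=(_o("out", "*.txt"),),
        requirements=(_sys("echo"),),
        origin=None,
    )


def _catalog() -> list[Recipe]:
    gcp_bundles = [
        (
            "gcp_broad_gatk_hg19",
            "Download file in GATK annotation bundle for hg19 from GCP",
            "gs://gcp-public-data--broad-references/hg19/v0",
        ),
        (
            "gcp_broad_gatk_hg38",
            "Download file in GATK annotation bundle for hg38 from GCP",
            "gs://gcp-public-data--broad-references/hg38/v0",
        ),
        (
            "gcp_gatk_mutect2_b37",
            "Download file in GATK mutect2 bundle for b37 from GCP",
            "gs://gatk-best-practices/somatic-b37",
        ),
        (
            "gcp_gatk_mutect2_hg38",
            "Download file in GATK mutect2 bundle for hg38 from GCP",
            "gs://gatk-best-practices/somatic-hg38",
        ),
    ]
    recipes = [echo_out_recipe()]
    recipes.append(
        Recipe(
            name="ensembl_liftover",
            version="1.0.0",
            description="Download and unzip genome liftover file from Ensembl",
            script_template=(
                "wget -c https://ftp.ensembl.org/pub/assembly_mapping/"
                "{{species}}/{{from}}_to_{{to}}.chain.gz\n"
                "gzip -d {{from}}_to_{{to}}.chain.gz\n"
            ),
            parameters=(
                _p("species", description="Ensembl species name, e.g. homo_sapiens"),
                _p("from", description="Source assembly, e.g. GRCh37"),
                _p("to", description="Target assembly, e.g. GRCh38"),
            ),
            outputs=(_o("chain", "*.chain"),),
            requirements=(_sys("wget"), _sys("gzip")),
            origin="https://ftp.ensembl.org/pub/assembly_mapping",
        )
    )
    for name, description, bucket in gcp_bundles:
        recipes.append(
            Recipe(
                name=name,
                version="1.0.0",
                description=description,
                script_template=f"gsutil cp {bucket}/{{{{filename}}}} .\n",
                parameters=(
                    _p("filename", description="File name within the bundle"),
                ),
                outputs=(_o("data", "*"),),
                requirements=(_conda("gsutil", "conda-forge::gsutil"),),
                origin=bucket,
            )
        )
    recipes.append(
        Recipe(
            name="gencode_annotation",
            version="1.0.0",
            description="Download and unzip annotation files from gencode",
            script_template=(
                "wget -c https://ftp.ebi.ac.uk/pub/databases/gencode/"
                "Gencode_{{species}}/release_{{version}}/"
                "gencode.v{{version}}.annotation.gtf.gz\n"
                "gzip -d gencode.v{{version}}.annotation.gtf.gz\n"
            ),
            parameters=(
                _p("species", description="human or mouse"),
                _p("version", description="GENCODE release, e.g. 42"),
            ),
            outputs=(_o("annotation", "*.gtf"),),
            requirements=(_sys("wget"), _sys("gzip")),
            origin="https://ftp.ebi.ac.uk/pub/databases/gencode",
        )
    )
    recipes.append(
        Recipe(
            name="gencode_genome_grch38",
            version="1.0.0",
            description="Download human genome GRCh38 from GENCODE release 42",
            script_template=(
                "wget -c https://ftp.ebi.ac.uk/pub/databases/gencode/"
                "Gencode_human/release_42/GRCh38.primary_assembly.genome.fa.gz\n"
                "gzip -d GRCh38.primary_assembly.genome.fa.gz\n"
            ),
            parameters=(),
            outputs=(_o("genome", "*.fa"),),
            requirements=(_sys("wget"), _sys("gzip")),
            origin=(
                "https://ftp.ebi.ac.uk/pub/databases/gencode/"
                "Gencode_human/release_42"
            ),
        )
    )
    recipes.append(
        Recipe(
            name="gencode_transcripts",
            version="1.0.0",
            description="Download, unzip, and index transcripts files from gencode",
            script_template=(
                "wget -c https://ftp.ebi.ac.uk/pub/databases/gencode/"
                "Gencode_{{species}}/release_{{version}}/"
                "gencode.v{{version}}.transcripts.fa.gz\n"
                "gzip -d gencode.v{{version}}.transcripts.fa.gz\n"
                "samtools faidx gencode.v{{version}}.transcripts.fa\n"
            ),
            parameters=(
                _p("species", description="human or mouse"),
                _p("version", description="GENCODE release, e.g. 42"),
            ),
            outputs=(
                _o("transcripts", "*.fa"),
                _o("index", "*.fa.fai", role="secondary"),
            ),
            requirements=(
                _sys("wget"),
                _sys("gzip"),
                _conda("samtools", "bioconda::samtools"),
            ),
            origin="https://ftp.ebi.ac.uk/pub/databases/gencode",
        )
    )
    recipes.append(
        Recipe(
            name="bowtie2_index",
            version="1.0.0",
            description='Use "bowtie2-build" to index a specific reference genome',
            script_template=(
                "bowtie2-build --threads {{threads}} {{fasta}} {{prefix}}\n"
            ),
            parameters=(
                _p("fasta", ptype="file", description="Reference genome fasta"),
                _p("prefix", description="Index basename"),
                _p("threads", ptype="int", required=False, default=4),
            ),
            outputs=(_o("index", "*.bt2"),),
            requirements=(_conda("bowtie2", "bioconda::bowtie2"),),
            origin="https://bowtie-bio.sourceforge.net/bowtie2",
        )
    )
    recipes.append(
        Recipe(
            name="hisat2_index",
            version="1.0.0",
            description='Use "hisat2-build" to build the index files',
            script_template="hisat2-build -p {{threads}} {{fasta}} {{prefix}}\n",
            parameters=(
                _p("fasta", ptype="file", description="Reference genome fasta"),
                _p("prefix", description="Index basename"),
                _p("threads", ptype="int", required=False, default=4),
            ),
            outputs=(_o("index", "*.ht2"),),
            requirements=(_conda("hisat2", "bioconda::hisat2"),),
            origin="http://daehwankimlab.github.io/hisat2",
        )
    )
    recipes.append(
        Recipe(
            name="salmon_index",
            version="1.0.0",
            description=(
                'Use "Salmon index" command to build salmon index for '
                "your transcriptome"
            ),
            script_template=(
                "salmon index -t {{transcriptome}} -i salmon_index -k {{kmer}}\n"
            ),
            parameters=(
                _p("transcriptome", ptype="file", description="Transcript fasta"),
                _p("kmer", ptype="int", required=False, default=31),
            ),
            outputs=(_o("index", "salmon_index/*"),),
            requirements=(_conda("salmon", "bioconda::salmon"),),
            origin="https://combine-lab.github.io/salmon",
        )
    )
    recipes.append(
        Recipe(
            name="STAR_index",
            version="1.0.0",
            description="Use STAR command to build genome index for STAR alignment",
            script_template=(
                "mkdir -p STAR_index\n"
                "STAR --runMode genomeGenerate --genomeDir STAR_index"
                " --genomeFastaFiles {{fasta}} --sjdbGTFfile {{gtf}}"
                " --sjdbOverhang {{overhang}} --runThreadN {{threads}}\n"
            ),
            parameters=(
                _p("fasta", ptype="file", description="Genome fasta"),
                _p("gtf", ptype="file", description="Gene annotation GTF"),
                _p("overhang", ptype="int", required=False, default=100),
                _p("threads", ptype="int", required=False, default=4),
            ),
            outputs=(_o("index", "STAR_index/*"),),
            requirements=(_conda("star", "bioconda::star"),),
            origin="https://github.com/alexdobin/STAR",
        )
    )
    recipes.append(
        Recipe(
            name="ucsc_database",
            version="1.0.0",
            description=(
                "Download genome annotation file from UCSC database using "
                "the golden path"
            ),
            script_template=(
                "wget -c https://hgdownload.soe.ucsc.edu/goldenPath/"
                "{{genome}}/database/{{filename}}.txt.gz\n"
                "gzip -d {{filename}}.txt.gz\n"
            ),
            parameters=(
                _p("genome", description="UCSC genome build, e.g. hg38"),
                _p("filename", description="Database table name, e.g. refGene"),
            ),
            outputs=(_o("table", "*.txt"),),
            requirements=(_sys("wget"), _sys("gzip")),
            origin="https://hgdownload.soe.ucsc.edu/goldenPath",
        )
    )
    recipes.append(
        Recipe(
            name="reference_genome",
            version="1.0.0",
            description=(
                "Download, format and index reference genome file with "
                "samtools, picard and bwa"
            ),
            script_template=(
                "wget -c {{url}} -O {{prefix}}.fa.gz\n"
                "gzip -d {{prefix}}.fa.gz\n"
                "samtools faidx {{prefix}}.fa\n"
                "picard CreateSequenceDictionary R={{prefix}}.fa O={{prefix}}.dict\n"
                "bwa index {{prefix}}.fa\n"
            ),
            parameters=(
                _p("url", description="URL of the gzipped genome fasta"),
                _p("prefix", description="Local basename for the genome"),
            ),
            outputs=(
                _o("genome", "*.fa"),
                _o("faidx", "*.fa.fai", role="secondary"),
                _o("dict", "*.dict", role="secondary"),
                _o("bwa_index", "*.fa.*", role="secondary"),
            ),
            requirements=(
                _sys("wget"),
                _conda("samtools", "bioconda::samtools"),
                _conda("picard", "bioconda::picard"),
                _conda("bwa", "bioconda::bwa"),
            ),
            origin="https://ftp.ensembl.org/pub",
        )
    )
    return recipes


def catalog_recipes() -> list[Recipe]:
    """The fifteen shipped recipes, sorted by name."""
    return sorted(_catalog(), key=lambda r: r.name)


CATALOG_NAMES = tuple(r.name for r in catalog_recipes())

#: recipes whose scripts run with no network (origin is local)
OFFLINE_RECIPES = tuple(r.name for r in catalog_recipes() if r.origin is None)


def make_catalog(dest: str | Path) -> list[Path]:
    """Write the shipped catalog, one ``<name>.yaml`` per recipe."""
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    return [
        write_recipe(recipe, dest / f"{recipe.name}.yaml")
        for recipe in catalog_recipes()
    ]


_NOTE_WORDS = (
    "human",
    "mouse",
    "genome",
    "liftover",
    "annotation",
    "transcripts",
    "variants",
    "reference",
    "index",
    "release",
)


def make_toy_data_tree(
    root: str | Path, n_records: int, seed: int = 0
) -> list[Path]:
    """Evaluate ``echo_out`` ``n_records`` times into a nested tree.

    Bindings and notes are drawn deterministically from ``seed``; the tree
    nests two levels deep so recursive sidecar scanning is exercised.
    Returns the sidecar paths.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    recipe = echo_out_recipe()
    sidecars: list[Path] = []
    for i in range(n_records):
        words = rng.sample(_NOTE_WORDS, 3)
        bindings = {
            "input": f"{words[0]} {words[1]} payload-{rng.randrange(10**6)}",
            "outfile": f"{words[0]}_{i:03d}",
        }
        notes = [f"{words[0]} {words[1]}", words[2]]
        outdir = root / f"group{i % 3}" / f"run{i:03d}"
        result = evaluate(recipe, bindings, outdir, notes=notes)
        sidecars.append(result.sidecars["yml"])
    return sidecars


def make_mock_bucket(
    bucket_dir: str | Path, entries: int, seed: int = 0
) -> Path:
    """Build a local-directory bucket of pre-built ``echo_out`` outputs.

    Writes ``entries`` small text files with true MD5 digests and the
    matching manifest TSV; returns the manifest path.
    """
    bucket_dir = Path(bucket_dir)
    bucket_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    rows = []
    for i in range(entries):
        word = rng.choice(_NOTE_WORDS)
        params = {"input": f"{word} cloud-{i}", "outfile": f"cloud{i:03d}"}
        rel = f"echo_out/{i:03d}/{params['outfile']}.txt"
        target = bucket_dir / rel
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_text(params["input"] + "\n")
        rows.append(
            "\t".join(
                [
                    "echo_out",
                    canonical_params(params),
                    rel,
                    compute_md5(target),
                    str(target.stat().st_size),
                ]
            )
        )
    manifest = bucket_dir / MANIFEST_NAME
    manifest.write_text(
        "\t".join(MANIFEST_COLUMNS) + "\n" + "".join(r + "\n" for r in rows)
    )
    return manifest
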
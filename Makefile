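.PHONY: test smoke

test:
	python -m pytest tests/ -q

# end-to-end CLI pipeline on a small synthetic dataset
smoke:
	rm -rf scratch/smoke && mkdir -p scratch/smoke
	printf 'monomer_names: [methane, water, methanol, methanethiol]\n' > scratch/smoke/config.yaml
	pairsapt simulate --out scratch/smoke/data --seed 7 --n-orientations 2 --config scratch/smoke/config.yaml
	pairsapt fit --manifest scratch/smoke/data/manifest.csv --out scratch/smoke/params.csv --trace scratch/smoke/trace.csv
	pairsapt predict --manifest scratch/smoke/data/manifest.csv --params scratch/smoke/params.csv --out scratch/smoke/preds.csv
	pairsapt evaluate --predictions scratch/smoke/preds.csv --manifest scratch/smoke/data/manifest.csv --out scratch/smoke/report.csv
	@cat scratch/smoke/report.csv
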
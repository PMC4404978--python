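taxon,genepool,accessions,accessions_georeferenced,gap_category,expert_category,clusters
Ipomoea batatas (wild),2,4,0,HPS,HPS,2
Ipomoea cordatotriloba,3,103,67,HPS,MPS,1
Ipomoea cynanchifolia,3,1,0,HPS,HPS,1;2
Ipomoea grandifolia,3,124,83,MPS,MPS,1
Ipomoea lacunosa,3,10,1,HPS,MPS,1
Ipomoea leucantha,3,18,15,HPS,MPS,1;2
Ipomoea littoralis,2,2,2,HPS,HPS,2
Ipomoea ramosissima,3,34,30,HPS,MPS,2;1
Ipomoea splendor-sylvae,3,16,9,HPS,HPS,2
Ipomoea tabascana,2,4,2,LPS,HPS,2
Ipomoea tenuissima,3,3,1,HPS,HPS,1
Ipomoea tiliacea,3,61,44,HPS,HPS,2
Ipomoea trifida,2,248,159,MPS,MPS,2
Ipomoea triloba,3,121,74,HPS,MPS,2;1
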
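# Simulation spec template for `phylocurate simulate trees --spec ...`
#
# Species tree layout: minor-clade prefix -> number of taxa. Prokaryote
# clades (Ba/Za) double as the rooting outgroup; keep at least one with
# two or more taxa. Omit to use the built-in 36-taxon default.
taxon_counts:
  Ba_pr: 3
  Za_eu: 3
  Op_me: 5
  Sr_ci: 6
  Ex_pa: 3
  EE_ha: 3

n_gfs: 20          # gene families to simulate
paralog_rate: 0.1  # per-leaf probability of a duplicated (paralog) cherry
dropout_rate: 0.2  # per-taxon, per-GF dropout (event lineages are exempt)

# Planted contamination events. Modes:
#   sister_single     one recipient-labeled leaf grafted as sole sister to
#                     a donor-lineage leaf, on a short terminal branch
#                     (terminal_branch_scale x mean terminal branch)
#   cherry_pair       a cherry of recipient + partner_taxon leaves,
#                     emulating two co-contaminated libraries
#   misassigned_clade a block of block_size recipient-labeled leaves
#                     inside the donor clade (wholesale misassignment)
events:
  - event_id: ev1
    recipient_taxon: Sr_ci_S019   # taxon codes follow the layout above
    donor_prefix: EE_ha           # food-source contamination
    mode: sister_single
    terminal_branch_scale: 0.25
    n_gfs_affected: 4
  - event_id: ev2
    recipient_taxon: Sr_ci_S017
    donor_prefix: Ba_pr           # bacterial contamination
    mode: sister_single
    n_gfs_affected: 4
  - event_id: ev3
    recipient_taxon: Op_me_S009
    partner_taxon: Op_me_S010
    donor_prefix: Ex_pa
    mode: cherry_pair
    n_gfs_affected: 3
  - event_id: ev4
    recipient_taxon: Sr_ci_S018
    donor_prefix: Ex_pa           # the rumen-ciliate-style misassignment
    mode: misassigned_clade
    block_size: 6
    n_gfs_affected: 3
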
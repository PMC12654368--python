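# Default descriptor-curation rules.
#
# Raw free-text odor descriptors are lowercased, trimmed, collapsed through
# synonym_map, mapped to semantic categories by category_map, sparse
# categories folded into broader ones by merge_map, and the winning category
# chosen by priority_order (earlier = higher priority). polarity_map then
# gives the binary aroma-contribution label per final category.
#
# The whole file is user-editable; the defaults below cover the descriptors
# common in flavor-volatile databases. "Odorless" is an explicit descriptor-
# derived category — it is never inferred from a missing descriptor list.

synonym_map:
  fruit: fruity
  fruit-like: fruity
  floral-like: floral
  flower: floral
  flowery: floral
  grass: grassy
  green: grassy
  herbal: herbaceous
  herb: herbaceous
  mint: minty
  menthol: cooling
  citrusy: citrus
  lemony: lemon
  butter: buttery
  cream: creamy
  vanilla-like: vanilla
  caramellic: caramel
  sulfur: sulfurous
  sulfury: sulfurous
  odourless: odorless
  no odor: odorless

category_map:
  fruity: Fruity
  apple: Fruity
  pear: Fruity
  banana: Fruity
  berry: Fruity
  tropical: Fruity
  citrus: Citrus
  lemon: Citrus
  orange: Citrus
  grapefruit: Citrus
  floral: Floral
  rose: Floral
  jasmine: Floral
  lavender: Floral
  sweet: Sweet/Vanilla/Caramel
  vanilla: Sweet/Vanilla/Caramel
  caramel: Sweet/Vanilla/Caramel
  honey: Sweet/Vanilla/Caramel
  buttery: Dairy/Buttery
  creamy: Dairy/Buttery
  dairy: Dairy/Buttery
  milky: Dairy/Buttery
  minty: Minty/Cooling
  cooling: Minty/Cooling
  camphoraceous: Minty/Cooling
  woody: Woody
  cedar: Woody
  pine: Woody
  grassy: Green/Herbal
  herbaceous: Green/Herbal
  leafy: Green/Herbal
  leaf: Green/Herbal
  vegetal: Green/Herbal
  rancid: Rancid/Sweaty/Animalic
  sweaty: Rancid/Sweaty/Animalic
  animalic: Rancid/Sweaty/Animalic
  fecal: Rancid/Sweaty/Animalic
  chemical: Chemical/Solvent/Plastic
  solvent: Chemical/Solvent/Plastic
  plastic: Chemical/Solvent/Plastic
  gasoline: Chemical/Solvent/Plastic
  musty: Musty/Moldy
  moldy: Musty/Moldy
  earthy: Musty/Moldy
  sulfurous: Sulfurous
  garlic: Sulfurous
  onion: Sulfurous
  odorless: Odorless

merge_map:
  Dairy/Buttery: Sweet/Vanilla/Caramel
  Rancid/Sweaty/Animalic: Off-flavor
  Chemical/Solvent/Plastic: Off-flavor
  Musty/Moldy: Off-flavor
  Sulfurous: Off-flavor

priority_order:
  - Fruity
  - Citrus
  - Floral
  - Sweet/Vanilla/Caramel
  - Minty/Cooling
  - Woody
  - Green/Herbal
  - Off-flavor
  - Odorless

polarity_map:
  Fruity: positive
  Citrus: positive
  Floral: positive
  Sweet/Vanilla/Caramel: positive
  Minty/Cooling: positive
  Woody: positive
  Green/Herbal: negative
  Off-flavor: negative
  Odorless: negative
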
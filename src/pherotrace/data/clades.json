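{
 "Apidae sensu lato": [
  "Colletes cunicularius",
  "Lasioglossum malachurum",
  "Lasioglossum zephyrum",
  "Osmia rufa",
  "Megachile rotundata",
  "Amegilla dawsoni",
  "Centris analis",
  "Apis mellifera",
  "Bombus terrestris",
  "Bombus impatiens",
  "Bombus hypnorum",
  "Melipona bicolor",
  "Melipona scutellaris",
  "Scaptotrigona depilis",
  "Friesella schrottkyi",
  "Schwarziana quadripunctata"
 ],
 "Megachile + Apidae sensu strictu": [
  "Megachile rotundata",
  "Amegilla dawsoni",
  "Centris analis",
  "Apis mellifera",
  "Bombus terrestris",
  "Bombus impatiens",
  "Bombus hypnorum",
  "Melipona bicolor",
  "Melipona scutellaris",
  "Scaptotrigona depilis",
  "Friesella schrottkyi",
  "Schwarziana quadripunctata"
 ],
 "Apidae sensu strictu": [
  "Amegilla dawsoni",
  "Centris analis",
  "Apis mellifera",
  "Bombus terrestris",
  "Bombus impatiens",
  "Bombus hypnorum",
  "Melipona bicolor",
  "Melipona scutellaris",
  "Scaptotrigona depilis",
  "Friesella schrottkyi",
  "Schwarziana quadripunctata"
 ],
 "Centris + Corbiculate bees": [
  "Centris analis",
  "Apis mellifera",
  "Bombus terrestris",
  "Bombus impatiens",
  "Bombus hypnorum",
  "Melipona bicolor",
  "Melipona scutellaris",
  "Scaptotrigona depilis",
  "Friesella schrottkyi",
  "Schwarziana quadripunctata"
 ],
 "Corbiculate bees": [
  "Apis mellifera",
  "Bombus terrestris",
  "Bombus impatiens",
  "Bombus hypnorum",
  "Melipona bicolor",
  "Melipona scutellaris",
  "Scaptotrigona depilis",
  "Friesella schrottkyi",
  "Schwarziana quadripunctata"
 ],
 "Meliponini": [
  "Melipona bicolor",
  "Melipona scutellaris",
  "Scaptotrigona depilis",
  "Friesella schrottkyi",
  "Schwarziana quadripunctata"
 ],
 "Bombini": [
  "Bombus terrestris",
  "Bombus impatiens",
  "Bombus hypnorum"
 ]
}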
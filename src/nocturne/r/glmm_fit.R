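# Poisson GLMM engine: count ~ fixed effects + (1 | group), log link,
# optional offset. Interface: Rscript glmm_fit.R <dir> with data.csv and
# config.json; writes result.json (one entry per replicate).
suppressMessages({
  library(lme4)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
dir <- args[[1]]
cfg <- fromJSON(file.path(dir, "config.json"), simplifyVector = FALSE)
dat <- read.csv(file.path(dir, "data.csv"))

response <- cfg$response
fixed <- unlist(cfg$fixed)
group <- cfg$group
offset_col <- cfg$offset
level <- if (is.null(cfg$ci_level)) 0.95 else cfg$ci_level
zcrit <- qnorm(1 - (1 - level) / 2)

rhs <- paste(c(fixed, sprintf("(1 | %s)", group)), collapse = " + ")
if (!is.null(offset_col)) rhs <- paste(rhs, sprintf("+ offset(%s)", offset_col))
form <- as.formula(paste(response, "~", rhs))

run_one <- function(d) {
  d[[group]] <- factor(d[[group]])
  fit <- glmer(form, data = d, family = poisson,
               control = glmerControl(check.conv.grad = .makeCC("warning", tol = 5e-3)))
  co <- summary(fit)$coefficients
  terms <- list()
  for (i in seq_len(nrow(co))) {
    est <- co[i, 1]; se <- co[i, 2]
    terms[[i]] <- list(term = rownames(co)[i], estimate = est, se = se,
                       z = co[i, 3], p = co[i, 4],
                       ci_lo = est - zcrit * se, ci_hi = est + zcrit * se)
  }
  vc <- as.data.frame(VarCorr(fit))
  list(terms = terms,
       random_sd = vc$sdcor[1],
       converged = length(fit@optinfo$conv$lme4$messages) == 0,
       n = nrow(d))
}

if ("replicate" %in% names(dat)) {
  reps <- sort(unique(dat$replicate))
  results <- lapply(reps, function(r) {
    out <- tryCatch(
      run_one(dat[dat$replicate == r, setdiff(names(dat), "replicate"), drop = FALSE]),
      error = function(e) list(error = conditionMessage(e)))
    out$replicate <- r
    out
  })
} else {
  results <- list(run_one(dat))
}

write(toJSON(results, auto_unbox = TRUE, digits = 12, na = "null"),
      file.path(dir, "result.json"))
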